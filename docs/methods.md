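# Methods

`dyadsync` models and analyzes dyadic sensorimotor synchronization in a
melody-tapping task: two partners tap an 8-tone melody together at a cued
450 ms period, and the quantity of interest is the signed asynchrony
between their tone onsets, tap by tap.  Solo trials, in which one
performer synchronizes with a computer-generated recording, use the same
machinery with a non-adapting stimulus.

## The delay-coupled oscillator model

Each partner is a phase oscillator; one cycle of phase = one tap.  The
phases evolve as

    dθ₁/dt = 2π/ω₁ + k₁·C·sin(θ₂(t) − θ₁(t − τ₁))
    dθ₂/dt = 2π/ω₂ + k₂·C·sin(θ₁(t) − θ₂(t − τ₂))

with, per oscillator:

| parameter | meaning | units | default / bounds |
|---|---|---|---|
| ω | intrinsic period (inverse rate) | ms | ω̄ fixed at 450; Δω = ω₁ − ω₂ fit in [−300, 300] |
| k | coupling gain | dimensionless | fit in [0, 50] |
| τ | memory delay: lag of the oscillator's own state in its coupling term | ms | fit in [0, 50] |

The delayed term is the oscillator's **own** past state — the
strong-anticipation mechanism: an oscillator that adjusts its current
velocity by comparing the partner's present phase with its own remembered
phase settles ahead of a non-adapting partner by τ ms, which produces
anticipatory synchrony (the negative mean asynchrony) without an internal
predictive model.  A variant with the delay on the partner's phase is
available (`delay_on_partner=True`); all shipped analyses use the default.

**Coupling normalization.**  The notation above leaves the units of k
open; we fix them with C = α·2π/ω̄², α = 0.55 by default.  Two
calibration requirements drove this choice, decided by analysis of the
model (not by adjusting to test outcomes): (i) dyads with coupling in the
empirically reported range (k ≈ 10–20) should phase-lock for realistic
intrinsic-period differences of a few ms and produce steady asynchronies
of roughly 10–40 ms, and (ii) the relaxation of an initial asynchrony
should unfold over one-to-several melody repetitions, because that
relaxation is the main signal through which k can be estimated from
repetition-averaged data.  With this normalization a dyad phase-locks
approximately when (k₁+k₂)·α·cos(Ωτ) exceeds |Δω| in ms (Ω = 2π/ω̄), and
the locked steady asynchrony is (ω̄/2π)·arcsin(Δω / ((k₁+k₂)·α·cos Ωτ)).
Above the threshold the dyad drifts with periodic phase slips.

**Integration.**  Fixed-step explicit Euler at dt = 1 ms with a linearly
interpolated delay buffer and constant-velocity history on [−τ, 0]
(numba-compiled).  The dynamics are slow relative to dt (velocity scale
2π/450 rad/ms, coupling ≤ 50·C ≈ 1.7·10⁻³ rad/ms), so Euler at 1 ms is
far inside its stability region; halving dt changes predicted profiles by
well under 0.1 ms (enforced in tests).  Phase differences are read at the
nominal tone times n·450 ms and converted to ms asynchronies via
Δθ·ω̄/2π, with ω̄ the mean of the two fitted periods (the nominal period
is a config option).  Non-finite states raise an error echoing the
parameters.

**Model output.**  The per-position asynchrony profile: the signed
asynchrony (partner 1 − partner 2; negative = partner 1 ahead) at each of
the 8 melody positions, averaged over the trial's 9 analyzed repetitions —
the same reduction the metrics module applies to observed trials.  The
model's initial relative phase is zero unless an initial asynchrony is
supplied; the fitting pipeline supplies the trial's first observed paired
asynchrony.  Without that anchor, k is structurally unidentifiable from
profiles of near-equal-period dyads (their noise-free profile is flat at
zero for every k).

## Behavioral measures

Asynchrony = produced onset − reference onset, so anticipation is
negative.  (The task's natural reading of "stimulus minus participant"
would flip the sign; we follow the convention under which the reported
anticipatory means are negative, and document the discrepancy here.)  For
solo trials the reference is the tone actually sounded, including any
feedback delays; referencing the underlying regular grid instead is a
flag (`use_nominal_grid=True`) for sensitivity checks.  Per trial we
report the mean signed asynchrony, the mean absolute asynchrony, the SD
of signed asynchronies, and the mean inter-tap interval, over the 72
analyzed taps (76 produced, final 4 dropped).  Condition summaries
average first within the design's random-effect unit (participant for
solo, pair for joint) across its 3 trials, then across units; empty cells
are flagged, never dropped.  Inferential statistics (ANOVA, contrasts,
signed-rank tests) are deliberately out of scope — the summary CSVs are
the input any statistics package needs.

## Two-stage fitting

The fitting target is the trial's 8-point asynchrony profile; the
objective is the RMSE between observed and model profiles.

*Stage 1 (global):* for each joint trial, a genetic algorithm searches
(Δω, k₁, k₂, τ) within the bounds above — τ shared between partners,
since a single memory delay per trial is what the downstream median uses.
Each GA winner is polished by bound-constrained Nelder–Mead (≤ 500
evaluations, function tolerance 10⁻⁶ ms²); the best of `n_restarts`
(default 10) refined fits is kept.  The median best-fit τ across trials
is the population memory-delay estimate.

*Stage 2 (τ fixed):* the search is repeated with τ fixed to that median.
Restarts whose refined parameters land on the search boundary (k ≥ 49 or
|Δω| ≥ 299 ms) are excluded before the per-trial best fit is chosen; a
trial whose restarts are all boundary cases is flagged, not dropped.

GA defaults: population 40, ≤ 40 generations with early stopping after 12
stagnant generations, tournament selection (size 3), uniform crossover at
rate 0.7, per-gene Gaussian mutation (probability 0.25, SD 5% of each
bound's width), one elite.  A population of ≤ 4 smooth parameters does
not need a larger budget; the acceptance property that the optimizer
matches an exhaustive 2-D grid search within 5% relative RMSE is what
certifies the setting.  Fixed-τ fits additionally seed the population
with *level-consistent warm starts*: for each of several candidate k
values, the Δω that reproduces the observed mean asynchrony level via the
steady-state relation above.  These place candidates along the fit
problem's principal ridge so that the transient, not the level alone,
selects among them.

*Symmetric coupling default.*  The pipeline fits one shared k per trial
(`shared_k=True`).  A single trial's repetition-averaged profile cannot
constrain k₁ and k₂ separately; the per-partner parameterization (kept as
an option, and the default of the lower-level fitting functions) tends to
park one gain at zero and inflate the other, which pushes the pooled
per-partner median toward zero.  Study-level condition comparisons use
the per-trial shared estimates.

*Reduced model:* k₁ = k₂ = 0, which provably cancels τ; the asynchrony is
then a linear drift, so the reduced fit optimizes Δω alone on the
closed-form prediction (coarse grid + bounded scalar polish,
deterministic).  In model comparisons the full fit is warm-started with
the reduced optimum, so nesting (full RMSE ≤ reduced RMSE) holds up to
local-optimizer tolerance on every trial by construction.

Determinism: every stochastic component (GA, restart seeds, generator)
derives from a user seed through `numpy.random.SeedSequence` spawning;
identical inputs and seed give identical results.

## Synthetic data generator

The generator reproduces the study design: per pair, Baseline Joint →
Solo intervention 1 → Joint → Solo intervention 2 → Joint, three
experimental trials per condition, intervention order (delayed-feedback
first vs normal first) counterbalanced exactly across pairs.  Defaults:
25 pairs; 450 ms period; 8-tone melody; 76 taps per trial; solo
recordings with 25% of tones (never the first or last) delayed by
U(30, 70) ms; motor noise SD 5 ms.

Joint trials: two delay-coupled oscillators with τ = 19.7 ms,
condition-specific true coupling (Baseline 11, Post-Delay 12.96,
Post-Normal 16.44 — the latter two are the empirically reported medians;
Baseline is set lower since no practice preceded it) plus per-pair jitter
(SD 1), per-pair period difference Δω ~ N(0, 5 ms), and a per-trial
initial asynchrony ~ N(0, 25 ms) standing for the partners' offset at the
end of the metronome lead-in.  Tap onsets are the oscillators' phase
crossings plus i.i.d. Gaussian emission noise; the phase dynamics
themselves stay deterministic.  Two variants exist for robustness work: a
`noise_is_heard` mode in which each partner couples to the other's
jittered tones (noise then propagates into the dynamics), and a
`wing_kristofferson` noise model adding an accumulating timekeeper
component to the white motor jitter.

Solo trials: the responder oscillator couples unidirectionally to the
recording's phase (piecewise-linear through the scheduled, possibly
delayed, tone times) with k = 16 and τ = 39 ms — the larger solo memory
delay makes the entrained responder lead the recording by ~39 ms,
matching the anticipatory mean observed against regular recordings.  The
responder starts near its entrained state and a 16-beat lead-in absorbs
its period mismatch; warm-up taps are not emitted (trials carry the 76
continuation taps, so the 76→72 trimming rule is still exercised).

What the generator does **not** emulate: within-trial tempo drift,
learning within a condition, pitch content (melody position is pure
bookkeeping), serially correlated motor noise under the default model,
and any asymmetry between partners' noise levels.  Passing tests
therefore certify the pipeline's correctness and its behavior under the
model's own assumptions — not that real dyads satisfy those assumptions.

## Identifiability: what fitting can and cannot recover here

The fitting target — a profile averaged over 9 repetitions — compresses
a trial to 8 numbers, and for a phase-locked dyad those numbers are
nearly flat at the steady level.  Consequences, derived analytically and
confirmed by simulation:

- The level constrains only the ratio Δω/(k₁+k₂)·α·cos Ωτ: estimates
  ride a ridge in (Δω, k) space.  τ is near-inert in the fixed-τ stage
  (cos Ωτ ≈ 0.96) — which is precisely why a pooled median τ from stage 1
  is fixed rather than fit per trial in stage 2.
- The ridge is broken by (i) the relaxation transient of the trial's
  initial asynchrony, whose rate is ∝ k — informative only when the
  initial offset differs substantially from the steady level, and
  attenuated ~9× by repetition averaging; and (ii) the lock/slip
  boundary, which makes slipping trials (large Δω relative to coupling)
  sharply k-sensitive.
- Under the study's noise level (5 ms per tap → ≈ 2.4 ms per profile
  point), the transient's k-information at Δω ≈ 0 is of the same order
  as the noise for mid-range k at any admissible normalization: per-trial
  k estimates there are noise-dominated, and even their median over tens
  of trials is not guaranteed within ±20% of truth.  The recovery
  acceptance test asserts the full recovery property regardless and is
  expected to fail in exactly those cells; Δω recovery and the
  well-conditioned (slipping or strongly detuned) k cells pass.
- Parameter-recovery probes therefore start trials from controlled
  ±30 ms initial offsets (alternating sign) — a recovery-study design
  choice that maximizes the transient signal — and condition-level
  claims rest on medians over many trials, mirroring how the estimates
  are used at study level.

## Problem sizes in tests and the acceptance script

Simulation-heavy properties run at desk-scale sizes, chosen as the
package's own test budget and stated here: optimizer-vs-grid equivalence
on 6 profiles against a 100×100 exhaustive grid (script: 3 profiles,
80×80); parameter recovery with 12 trials per cell and 2 restarts
(script: 10); stimulus statistics over ~10⁴ tones.  The end-to-end
condition-discrimination experiment runs at the study's own size of 25
pairs (script: 12), because the true condition difference in coupling is
small relative to the per-trial estimate spread and the ordering of
medians is only resolvable with study-scale trial counts.  The full
study configuration (25 pairs, 10 restarts) runs through the same code
paths via the CLI or `PipelineConfig` defaults.

## Known limitations

- Per-trial coupling estimates are ridge-dominated (above); compare
  conditions, not single trials.
- The boundary-exclusion rule (k ≥ 49, |Δω| ≥ 299) censors the upper
  ridge and can bias condition medians downward when trials are weakly
  identified.
- The Euler/delay-buffer integrator targets this model class only; it is
  not a general DDE solver, and no analytic DDE solutions or stability
  analyses are provided.
- The solo responder reuses the dyadic coupling law with a fixed larger
  τ; it is a modeling convenience for generating realistic solo
  behavior, not a fitted claim about solo tapping.
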