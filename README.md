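# dyadsync

Delay-coupled oscillator analysis of dyadic tapping synchronization.

When two musicians tap a melody together, each adapts the timing of their
taps to the tones they hear from their partner.  `dyadsync` is a Python
toolkit for studying this kind of joint sensorimotor synchronization in
the synchronization–continuation paradigm: an 8-tone melody tapped at a
450 ms cued period, either with a partner (joint trials) or with a
computer-generated recording that is temporally regular or contains
occasional (25%) tone delays of 30–70 ms (solo trials).  It is written
for timing researchers who want to go from raw tap-onset files to
condition-level behavioral statistics and dynamical-model parameters.

The package provides:

- **Trial I/O** — a documented CSV interchange format for tap-onset
  data with validation, trimming (76 produced taps → 72 analyzed) and
  tap-by-tap dyad pairing;
- **Behavioral metrics** — signed asynchronies (negative =
  anticipation), their SD and absolute value, inter-tap intervals,
  per-melody-position asynchrony profiles, and condition summaries
  aggregated the way the design's random effects demand;
- **A delay-coupled two-oscillator model** of joint tapping,

      θ̇₁ = 2π/ω₁ + k₁·C·sin(θ₂(t) − θ₁(t − τ₁))
      θ̇₂ = 2π/ω₂ + k₂·C·sin(θ₁(t) − θ₂(t − τ₂))

  where ωᵢ are the partners' intrinsic periods (ms), kᵢ ∈ [0, 50]
  dimensionless coupling gains, and τᵢ ∈ [0, 50] ms "memory" delays on
  each oscillator's own past state — the strong-anticipation mechanism
  by which tapping ahead of a partner emerges without an internal
  predictive model;
- **A two-stage fitting pipeline** — genetic-algorithm global search
  plus constrained local refinement, best of 10 restarts per trial;
  stage 1 fits (Δω, k, τ) and pools the median τ across trials, stage 2
  refits (Δω, k) with τ fixed to that median and excludes
  parameter-boundary fits (k ≥ 49, |Δω| ≥ 299 ms) — and a nested-model
  comparison against the coupling-free (k = 0) variant;
- **A synthetic experiment generator** with known ground truth that
  reproduces the full counterbalanced design (Baseline Joint → Solo →
  Joint → Solo → Joint, 3 trials per condition), so every stage of the
  pipeline is testable without any data download.

See `docs/methods.md` for the model's assumptions, the coupling
normalization, estimation design, and known identifiability limits.

## Worked example

Fit the delay-coupled model to one synthetic joint trial
(`examples/03_fit_joint_trial.py`):

```text
observed profile (ms): [27.9 30.1 29.7 35.7 31.9 33.1 35.7 33. ]
truth:     k = 15.00   Δω =  +8.00 ms   Δω/k = +0.533
recovered: k = 29.34   Δω = +14.47 ms   Δω/k = +0.493
           (RMSE 1.59 ms, 3/3 restarts kept)
```

The observed profile is the trial's mean signed asynchrony (partner 1 −
partner 2) at each of the 8 melody positions, averaged over 9 melody
repetitions.  The fit reproduces it to 1.59 ms RMSE.  Note what is and
is not determined: the steady asynchrony level pins the *ratio* Δω/k
tightly (+0.533 true vs +0.493 recovered), while k itself is only
loosely constrained by a single trial — condition-level conclusions rest
on medians over many trials.

Behavioral summaries of a small synthetic session
(`examples/02_behavioral_metrics.py`):

```text
       task        order  mean_signed_asynchrony_ms_mean  sd_signed_asynchrony_ms_mean
solo_normal  delay_first                           -35.0                           4.9
solo_normal normal_first                           -42.8                           4.8
 solo_delay  delay_first                           -36.4                          22.6
 solo_delay normal_first                           -44.8                          22.7

task_class  mean_absolute_asynchrony_ms   se
     joint                         9.05 0.46
      solo                        39.76 4.05
```

Solo tapping anticipates the recording by ~40 ms (the negative mean
asynchrony); occasional delayed feedback inflates the asynchrony SD
several-fold; and partners synchronize with each other far better than
with a regular recording — the bidirectional-coupling advantage.

The other scripts in `examples/` walk through the forward model
(`01_simulate_dyad.py`), the nested-model comparison
(`04_model_comparison.py`) and the full two-stage pipeline on a
multi-pair experiment (`05_full_experiment.py`).

A thin CLI mirrors the pipeline for shell use:

```sh
dyadsync simulate --n-pairs 4 --seed 0 --out session/
dyadsync report --in session/ --out tables/
```

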