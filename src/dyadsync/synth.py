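"""Synthetic experiment generator with known ground truth.

Emulates the study design end to end: synchronization–continuation trials
at a 450 ms cued period on an 8-tone melody, 76 produced taps per trial
(the final 4 dropped at analysis), solo trials in which a responder
oscillator synchronizes with a computer-generated recording (temporally
regular, or with 25% of tones delayed by 30–70 ms), and joint trials
produced by two mutually delay-coupled noisy oscillators.  Each pair
performs Baseline Joint, a first Solo intervention, Joint, the second Solo
intervention, and Joint again, with the intervention order counterbalanced
across pairs and 3 experimental trials per condition.

Every generated file passes the I/O module's validation, and the ground
truth (true coupling/period/delay parameters, noise-free skeleton
asynchronies, stimulus schedules) is stored alongside so that every
pipeline stage can be tested against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from ._core import TWO_PI, integrate_driven, integrate_pair
from .model import COUPLING_ALPHA, DCSParameters, coupling_constant
from .trials import (
    DyadSyncError,
    DyadTrial,
    ORDERS,
    StimulusSchedule,
    TapTrial,
    write_trials,
)


@dataclass(frozen=True)
class SoloResponder:
    """Unidirectional oscillator synchronizing with a recording.

    Same coupling law as the dyad model with the stimulus as a
    non-adapting oscillator.  The default memory delay is larger than the
    dyadic one so that the responder shows the strong negative mean
    asynchrony (~ −39 ms) humans produce against regular recordings.
    """

    omega_ms: float = 450.0
    k: float = 16.0
    tau_ms: float = 39.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic experiment."""

    n_pairs: int = 25
    period_ms: float = 450.0
    melody_length: int = 8
    n_taps: int = 76  # produced taps per trial (9.5 melody repetitions)
    delay_fraction: float = 0.25
    delay_range_ms: tuple[float, float] = (30.0, 70.0)
    motor_noise_sd_ms: float = 5.0
    initial_asynchrony_sd_ms: float = 25.0
    delta_omega_sd_ms: float = 5.0  # spread of partners' period difference
    # (small: both partners are musicians holding a cued 450 ms tempo; with
    # the default coupling normalization this keeps typical dyads phase-locked)
    tau_ms: float = 19.7
    solo_k: float = 16.0
    solo_tau_ms: float = 39.0
    # true coupling per joint condition (post-normal > post-delay, mirroring
    # the fitted medians; baseline lower: no preceding practice)
    joint_k: Mapping[str, float] = field(
        default_factory=lambda: {
            "joint_baseline": 11.0,
            "joint_post_delay": 12.96,
            "joint_post_normal": 16.44,
        }
    )
    k_pair_jitter_sd: float = 1.0
    n_trials_per_condition: int = 3
    #: if True, partners couple to the jittered tones they hear, so motor
    #: noise propagates into the dyad's dynamics; by default noise is purely
    #: an output (emission) jitter and the phase dynamics stay deterministic
    noise_is_heard: bool = False
    #: "gaussian": i.i.d. jitter on emitted onsets (default);
    #: "wing_kristofferson": two-level variant adding an accumulating
    #: timekeeper component (sd timekeeper_sd_ms per tap) to the white
    #: motor jitter, for robustness checks against correlated timing noise
    noise_model: str = "gaussian"
    timekeeper_sd_ms: float = 2.0
    coupling_alpha: float = COUPLING_ALPHA
    dt_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_ms <= 0 or self.n_taps < self.melody_length:
            raise DyadSyncError("invalid period or tap count")
        if not 0 <= self.delay_fraction < 1:
            raise DyadSyncError("delay_fraction must be in [0, 1)")
        lo, hi = self.delay_range_ms
        if lo <= 0 or hi < lo:
            raise DyadSyncError("invalid delay range")


def make_stimulus(
    config: GeneratorConfig,
    delayed: bool,
    rng: np.random.Generator,
    n_tones: int | None = None,
) -> StimulusSchedule:
    """Planned tone onsets of the recording; optionally 25% delayed tones.

    Delayed positions are drawn pseudo-randomly among the eligible tones
    (never the first or last of the trial), each with an independent
    uniform delay in the configured range.
    """
    n = int(n_tones if n_tones is not None else config.n_taps)
    onsets = np.arange(n) * config.period_ms
    delays: dict[int, float] = {}
    if delayed:
        n_delayed = int(round(config.delay_fraction * n))
        eligible = np.arange(1, n - 1)
        if n_delayed > eligible.size:
            raise DyadSyncError(
                f"cannot place {n_delayed} delays among {eligible.size} eligible tones"
            )
        positions = rng.choice(eligible, size=n_delayed, replace=False)
        lo, hi = config.delay_range_ms
        for pos in sorted(int(p) for p in positions):
            delays[pos] = float(rng.uniform(lo, hi))
        onsets = onsets.astype(float)
        for pos, d in delays.items():
            onsets[pos] += d
    return StimulusSchedule(
        nominal_period_ms=config.period_ms,
        melody_length=config.melody_length,
        tone_onsets_ms=onsets,
        delays_ms=delays,
    )


def _stimulus_phase_on_grid(
    schedule: StimulusSchedule, tgrid: np.ndarray, warmup_tones: int
) -> np.ndarray:
    """Piecewise-linear stimulus phase through tone times (2π per tone),
    extended backwards over the metronome lead-in and forwards at the
    nominal rate."""
    P = schedule.nominal_period_ms
    pre_times = -np.arange(warmup_tones, 0, -1) * P
    times = np.concatenate([pre_times, schedule.tone_onsets_ms])
    phases = TWO_PI * np.arange(-warmup_tones, schedule.n_tones)
    th = np.interp(tgrid, times, phases)
    # linear extrapolation outside the tone span
    before = tgrid < times[0]
    after = tgrid > times[-1]
    th[before] = phases[0] + (tgrid[before] - times[0]) * TWO_PI / P
    th[after] = phases[-1] + (tgrid[after] - times[-1]) * TWO_PI / P
    return th


def _emission_noise(
    rng: np.random.Generator, config: GeneratorConfig, n: int
) -> np.ndarray:
    """Per-tap onset noise under the configured noise model."""
    white = rng.normal(0.0, config.motor_noise_sd_ms, size=n)
    if config.noise_model == "gaussian":
        return white
    if config.noise_model == "wing_kristofferson":
        walk = np.cumsum(rng.normal(0.0, config.timekeeper_sd_ms, size=n))
        return white + walk
    raise DyadSyncError(f"unknown noise model {config.noise_model!r}")


def _enforce_increasing(onsets: np.ndarray, min_gap: float = 0.1) -> np.ndarray:
    out = onsets.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1] + min_gap:
            out[i] = out[i - 1] + min_gap
    return out


def make_solo_trial(
    schedule: StimulusSchedule,
    responder: SoloResponder,
    rng: np.random.Generator,
    config: GeneratorConfig,
    pair_id: str,
    performer_id: str,
    task: str,
    order: str,
    trial_index: int,
) -> tuple[TapTrial, dict]:
    """Simulate one performer synchronizing with a recording.

    The responder warms up against the regular lead-in (16 beats: metronome
    plus cued tapping) before the analyzed window, so it enters the trial
    entrained with its characteristic anticipatory lead.  Emitted onsets get
    i.i.d. Gaussian motor noise.  Returns the trial and its ground truth.
    """
    if responder.k < 0 or responder.tau_ms < 0 or responder.omega_ms <= 0:
        raise DyadSyncError("invalid responder parameters")
    P = schedule.nominal_period_ms
    dt = config.dt_ms
    warmup_tones = 16
    warmup = warmup_tones * P
    t_end = (schedule.n_tones + 1) * max(P, responder.omega_ms)
    n_steps = int(np.ceil((warmup + t_end) / dt))
    tgrid = np.arange(n_steps + 1) * dt - warmup
    theta_stim = _stimulus_phase_on_grid(schedule, tgrid, warmup_tones)

    cscale = coupling_constant(P, config.coupling_alpha)
    # start near the entrained state: the responder leads the recording by
    # its memory delay τ (the strong-anticipation equilibrium), so the
    # lead-in only has to absorb the responder's period mismatch
    th0 = theta_stim[0] + responder.tau_ms * TWO_PI / P
    th = integrate_driven(
        responder.omega_ms, responder.k, responder.tau_ms, cscale,
        th0, dt, n_steps, theta_stim,
    )
    # the kernel's internal clock starts at 0 = lead-in start; shift handled
    # via tgrid.  Tap m = crossing of phase 2π·m.
    targets = TWO_PI * np.arange(schedule.n_tones)
    crossings = np.interp(targets, th, tgrid)
    skeleton_asyn = crossings - schedule.tone_onsets_ms
    noise = _emission_noise(rng, config, crossings.size)
    # stored trial clock: one nominal period of headroom keeps onsets positive
    onsets = _enforce_increasing(crossings + noise + P)
    trial = TapTrial(
        pair_id=pair_id, performer_id=performer_id, task=task,
        order=order, trial_index=trial_index, onsets_ms=onsets,
    )
    truth = {
        "responder": asdict(responder),
        "skeleton_asynchronies_ms": skeleton_asyn.tolist(),
        "noise_ms": noise.tolist(),
        "delayed_positions": sorted(schedule.delays_ms),
    }
    return trial, truth


def make_joint_trial(
    params: DCSParameters,
    rng: np.random.Generator,
    config: GeneratorConfig,
    pair_id: str,
    task: str,
    order: str,
    trial_index: int,
    initial_asynchrony_ms: float | None = None,
) -> tuple[DyadTrial, dict]:
    """Simulate two mutually coupled noisy oscillators tapping together.

    Each partner's emitted tone carries Gaussian onset jitter, and partners
    couple to the tones they hear, so motor noise propagates into the
    dyad's dynamics.  The trial starts from a relative phase offset (drawn
    from the configured spread unless given) that stands for the partners'
    asynchrony at the end of the metronome lead-in.
    """
    P = config.period_ms
    dt = config.dt_ms
    n_taps = config.n_taps
    if initial_asynchrony_ms is None:
        initial_asynchrony_ms = float(rng.normal(0.0, config.initial_asynchrony_sd_ms))
    psi0 = initial_asynchrony_ms * TWO_PI / P
    th10, th20 = -0.5 * psi0, 0.5 * psi0

    eps1 = np.concatenate([_emission_noise(rng, config, n_taps), [0.0, 0.0]])
    eps2 = np.concatenate([_emission_noise(rng, config, n_taps), [0.0, 0.0]])
    heard1 = eps1 if config.noise_is_heard else np.zeros_like(eps1)
    heard2 = eps2 if config.noise_is_heard else np.zeros_like(eps2)
    cscale = coupling_constant(params.mean_period_ms, config.coupling_alpha)
    t_end = (n_taps + 1) * max(P, params.omega1_ms, params.omega2_ms)
    n_steps = int(np.ceil(t_end / dt))
    th1, th2 = integrate_pair(
        params.omega1_ms, params.omega2_ms, params.k1, params.k2,
        params.tau1_ms, params.tau2_ms, cscale, th10, th20,
        dt, n_steps, P, heard1, heard2, False,
    )
    tgrid = np.arange(n_steps + 1) * dt
    targets = TWO_PI * np.arange(n_taps)
    onsets = []
    for th, th0, om, eps in (
        (th1, th10, params.omega1_ms, eps1),
        (th2, th20, params.omega2_ms, eps2),
    ):
        cross = np.interp(targets, th, tgrid)
        pre = targets < th[0]  # crossings before t=0 (leading partner)
        cross[pre] = (targets[pre] - th0) * om / TWO_PI
        onsets.append(_enforce_increasing(cross + eps[:n_taps] + P))

    common = dict(pair_id=pair_id, task=task, order=order, trial_index=trial_index)
    trial_a = TapTrial(performer_id="A", onsets_ms=onsets[0], **common)
    trial_b = TapTrial(performer_id="B", onsets_ms=onsets[1], **common)
    dyad = DyadTrial(trial_a, trial_b, config.melody_length)
    truth = {
        "params": asdict(params),
        "initial_asynchrony_ms": initial_asynchrony_ms,
        "coupling_alpha": config.coupling_alpha,
    }
    return dyad, truth


@dataclass
class SyntheticExperiment:
    """All trials of a generated multi-pair session plus ground truth."""

    config: GeneratorConfig
    trials: list[TapTrial]
    schedules: dict[str, StimulusSchedule]
    truth: dict[str, dict]

    def joint_dyads(self) -> list[DyadTrial]:
        from .trials import JOINT_TASKS, pair_dyad

        by_key: dict[tuple, dict[str, TapTrial]] = {}
        for t in self.trials:
            if t.task in JOINT_TASKS:
                by_key.setdefault(
                    (t.pair_id, t.task, t.order, t.trial_index), {}
                )[t.performer_id] = t
        return [
            pair_dyad(d["A"], d["B"], self.config.melody_length)
            for d in by_key.values()
            if len(d) == 2
        ]

    def write(self, out_dir: str | Path) -> Path:
        """Write trials CSV, sidecar metadata, and ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "trials.csv"
        sched_meta = {
            key: {
                "tone_onsets_ms": s.tone_onsets_ms.tolist(),
                "delays_ms": {str(k): v for k, v in s.delays_ms.items()},
                "nominal_period_ms": s.nominal_period_ms,
                "melody_length": s.melody_length,
            }
            for key, s in self.schedules.items()
        }
        cfg = asdict(self.config)
        cfg["joint_k"] = dict(cfg["joint_k"])
        write_trials(
            self.trials, csv_path,
            metadata={"seed": self.config.seed, "config": cfg, "schedules": sched_meta},
        )
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return csv_path


def trial_key(pair_id: str, performer_id: str, task: str, trial_index: int) -> str:
    return f"{pair_id}:{performer_id}:{task}:{trial_index}"


def make_experiment(config: GeneratorConfig) -> SyntheticExperiment:
    """Generate the full counterbalanced experiment for all pairs.

    Condition sequence per pair: Baseline Joint, Solo 1 (both partners),
    Joint, Solo 2, Joint; half the pairs do the delayed-feedback solo first.
    Practice trials are not emitted.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    trials: list[TapTrial] = []
    schedules: dict[str, StimulusSchedule] = {}
    truth: dict[str, dict] = {}

    for p in range(config.n_pairs):
        pair_id = f"P{p + 1:02d}"
        order = ORDERS[p % 2]  # exact counterbalance across pairs
        dA = float(rng.normal(0.0, config.delta_omega_sd_ms / np.sqrt(2)))
        dB = float(rng.normal(0.0, config.delta_omega_sd_ms / np.sqrt(2)))
        omega_a, omega_b = config.period_ms + dA, config.period_ms + dB

        if order == "delay_first":
            solo_seq = ["solo_delay", "solo_normal"]
            joint_seq = ["joint_baseline", "joint_post_delay", "joint_post_normal"]
        else:
            solo_seq = ["solo_normal", "solo_delay"]
            joint_seq = ["joint_baseline", "joint_post_normal", "joint_post_delay"]

        # interleave: joint, solo, joint, solo, joint
        phases = [
            ("joint", joint_seq[0]), ("solo", solo_seq[0]),
            ("joint", joint_seq[1]), ("solo", solo_seq[1]),
            ("joint", joint_seq[2]),
        ]
        for kind, task in phases:
            if kind == "joint":
                k_true = config.joint_k[task] + float(
                    rng.normal(0.0, config.k_pair_jitter_sd)
                )
                k_true = max(k_true, 0.0)
                params = DCSParameters(
                    omega_a, omega_b, k_true, k_true, config.tau_ms, config.tau_ms
                )
                for tr in range(1, config.n_trials_per_condition + 1):
                    dyad, info = make_joint_trial(
                        params, rng, config, pair_id, task, order, tr
                    )
                    trials.extend([dyad.trial_a, dyad.trial_b])
                    truth[f"{pair_id}:{task}:{tr}"] = info
            else:
                delayed = task == "solo_delay"
                for performer_id, omega in (("A", omega_a), ("B", omega_b)):
                    responder = SoloResponder(
                        omega_ms=omega, k=config.solo_k, tau_ms=config.solo_tau_ms
                    )
                    for tr in range(1, config.n_trials_per_condition + 1):
                        sched = make_stimulus(config, delayed, rng)
                        key = trial_key(pair_id, performer_id, task, tr)
                        schedules[key] = sched
                        trial, info = make_solo_trial(
                            sched, responder, rng, config,
                            pair_id, performer_id, task, order, tr,
                        )
                        trials.append(trial)
                        truth[key] = info
    return SyntheticExperiment(config, trials, schedules, truth)
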