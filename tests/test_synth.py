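"""Synthetic experiment generator: stimulus statistics, trial dynamics,
counterbalancing, and generator–fitter consistency."""

import numpy as np
import pytest

from dyadsync.fitting import fit_reduced
from dyadsync.metrics import asynchrony_profile, signed_asynchronies, trial_summary
from dyadsync.model import DCSParameters, simulate
from dyadsync.synth import (
    GeneratorConfig,
    SoloResponder,
    make_experiment,
    make_joint_trial,
    make_solo_trial,
    make_stimulus,
)
from dyadsync.trials import ORDERS, pair_dyad, read_trials, trim_trial


class TestStimulus:
    def test_regular_schedule_is_exact_grid(self, gen_config, rng):
        s = make_stimulus(gen_config, delayed=False, rng=rng)
        assert np.array_equal(s.tone_onsets_ms, np.arange(76) * 450.0)
        assert not s.delayed_positions

    def test_delayed_schedule_counts_and_ranges(self, gen_config, rng):
        s = make_stimulus(gen_config, delayed=True, rng=rng, n_tones=72)
        assert len(s.delayed_positions) == 18  # exactly 25% of 72
        assert 0 not in s.delayed_positions and 71 not in s.delayed_positions
        for d in s.delays_ms.values():
            assert 30.0 <= d <= 70.0

    def test_empirical_delay_mean_converges(self, gen_config):
        # law of large numbers at ~10⁴ tones: mean delay → 50 ms
        rng = np.random.default_rng(7)
        delays = []
        for _ in range(140):
            s = make_stimulus(gen_config, delayed=True, rng=rng)
            delays.extend(s.delays_ms.values())
        assert len(delays) > 2500
        assert np.mean(delays) == pytest.approx(50.0, abs=1.0)

    def test_determinism(self, gen_config):
        a = make_stimulus(gen_config, True, np.random.default_rng(3))
        b = make_stimulus(gen_config, True, np.random.default_rng(3))
        assert np.array_equal(a.tone_onsets_ms, b.tone_onsets_ms)
        assert a.delays_ms == b.delays_ms


class TestSoloTrials:
    def _solo(self, config, delayed=False, seed=0, responder=None):
        rng = np.random.default_rng(seed)
        sched = make_stimulus(config, delayed, rng)
        trial, truth = make_solo_trial(
            sched, responder or SoloResponder(), rng, config,
            "P01", "A", "solo_delay" if delayed else "solo_normal",
            "delay_first", 1,
        )
        return trial, sched, truth

    def test_entrainment_to_regular_schedule(self):
        # no noise, strong coupling: asynchrony settles to a constant
        # anticipatory lead equal to the responder's memory delay
        cfg = GeneratorConfig(motor_noise_sd_ms=0.0, seed=0)
        trial, sched, _ = self._solo(cfg, responder=SoloResponder(tau_ms=39.0))
        asyn = signed_asynchronies(
            trim_trial(trial).onsets_ms - 450.0, sched.tone_onsets_ms[:72]
        )
        assert np.std(asyn[40:]) < 0.5
        assert np.mean(asyn[40:]) == pytest.approx(-39.0, abs=2.0)

    def test_zero_coupling_drifts_at_delta_per_event(self):
        cfg = GeneratorConfig(motor_noise_sd_ms=0.0, seed=0)
        responder = SoloResponder(omega_ms=460.0, k=0.0, tau_ms=0.0)
        trial, sched, _ = self._solo(cfg, responder=responder)
        asyn = signed_asynchronies(
            trim_trial(trial).onsets_ms - 450.0, sched.tone_onsets_ms[:72]
        )
        inc = np.diff(asyn)
        assert np.allclose(inc, 10.0, atol=0.5)

    def test_delayed_feedback_inflates_variability(self):
        # paired comparison at matched motor noise: the occasionally-delayed
        # recording yields a larger asynchrony SD than the regular one
        cfg = GeneratorConfig(seed=0)
        sds = {}
        for delayed in (False, True):
            trial, sched, _ = self._solo(cfg, delayed=delayed, seed=11)
            s = trial_summary(trim_trial(trial), sched)
            sds[delayed] = s.sd_signed_asynchrony_ms
        assert sds[True] > 2.0 * sds[False]

    def test_ground_truth_recorded(self, gen_config):
        trial, sched, truth = self._solo(gen_config, delayed=True, seed=2)
        assert len(truth["skeleton_asynchronies_ms"]) == 76
        assert truth["delayed_positions"] == sorted(sched.delays_ms)


class TestJointTrials:
    def test_symmetric_zero_noise_profile_decays_to_zero(self):
        cfg = GeneratorConfig(motor_noise_sd_ms=0.0, seed=0)
        p = DCSParameters.from_delta(0.0, 16.0, 16.0, 19.7)
        dyad, _ = make_joint_trial(
            p, np.random.default_rng(1), cfg, "P01", "joint_baseline",
            "delay_first", 1, initial_asynchrony_ms=30.0,
        )
        asyn = pair_dyad(trim_trial(dyad.trial_a), trim_trial(dyad.trial_b)).asynchronies_ms
        assert abs(asyn[0]) > 20.0
        assert np.max(np.abs(asyn[-16:])) < 1.0

    def test_noise_free_drift_trial_fit_recovers_delta(self):
        # deterministic drift trial: the reduced fit returns Δω = 10 ± 1 ms
        cfg = GeneratorConfig(motor_noise_sd_ms=0.0, seed=0)
        p = DCSParameters.from_delta(10.0, 0.0, 0.0, 0.0)
        dyad, _ = make_joint_trial(
            p, np.random.default_rng(2), cfg, "P01", "joint_baseline",
            "delay_first", 1, initial_asynchrony_ms=0.0,
        )
        prof = asynchrony_profile(
            pair_dyad(trim_trial(dyad.trial_a), trim_trial(dyad.trial_b))
        )
        fit = fit_reduced(prof)
        assert fit.params.delta_omega_ms == pytest.approx(10.0, abs=1.0)

    def test_generator_skeleton_matches_forward_model(self):
        # crossing-time bookkeeping of the generator agrees with the model's
        # phase-difference readout at the nominal tone times
        cfg = GeneratorConfig(motor_noise_sd_ms=0.0, seed=0)
        p = DCSParameters.from_delta(6.0, 14.0, 14.0, 19.7)
        dyad, _ = make_joint_trial(
            p, np.random.default_rng(3), cfg, "P01", "joint_baseline",
            "delay_first", 1, initial_asynchrony_ms=25.0,
        )
        observed = pair_dyad(
            trim_trial(dyad.trial_a), trim_trial(dyad.trial_b)
        ).asynchronies_ms
        pred = simulate(p, n_events=72, initial_asynchrony_ms=25.0)
        assert np.max(np.abs(observed - pred.event_asynchronies_ms)) < 1.0


class TestExperiment:
    def test_counterbalance_and_structure(self):
        exp = make_experiment(GeneratorConfig(n_pairs=2, seed=5))
        orders = {t.order for t in exp.trials}
        assert orders == set(ORDERS)
        per_pair = [t for t in exp.trials if t.pair_id == "P01"]
        # 3 joint conditions × 3 trials × 2 performers + 2 solo × 2 × 3
        assert len(per_pair) == 30
        assert all(t.n_taps == 76 for t in exp.trials)
        # delay-first pair performs solo_delay before solo_normal trials exist
        tasks = {t.task for t in per_pair}
        assert {"joint_baseline", "joint_post_delay", "joint_post_normal",
                "solo_delay", "solo_normal"} == tasks

    def test_written_session_passes_validation_and_is_deterministic(self, tmp_path):
        cfg = GeneratorConfig(n_pairs=2, seed=9)
        p1 = make_experiment(cfg).write(tmp_path / "a")
        p2 = make_experiment(cfg).write(tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
        trials = read_trials(p1)  # full validation on read
        assert len(trials) == 60

    def test_truth_contains_condition_parameters(self):
        exp = make_experiment(GeneratorConfig(n_pairs=1, seed=3))
        joint_keys = [k for k in exp.truth if "joint" in k]
        assert len(joint_keys) == 9
        info = exp.truth[joint_keys[0]]
        assert set(info["params"]) >= {"omega1_ms", "k1", "tau1_ms"}
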