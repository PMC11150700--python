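"""Behavioral asynchrony measures against hand computations and brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync.metrics import (
    asynchrony_profile,
    condition_summaries,
    signed_asynchronies,
    solo_vs_joint_table,
    summaries_frame,
    trial_summary,
)
from dyadsync.trials import (
    DyadSyncError,
    StimulusSchedule,
    TapTrial,
    pair_dyad,
)


def _trial(onsets, task="joint_baseline", performer="A", order="delay_first",
           pair="P01", trial=1):
    return TapTrial(pair, performer, task, order, trial, np.asarray(onsets, float))


def _dyad(asyn, melody_length=8):
    """Dyad whose A−B asynchrony equals the given per-tap sequence."""
    base = np.arange(len(asyn)) * 450.0 + 1000.0
    a = _trial(base + np.asarray(asyn), performer="A")
    b = _trial(base, performer="B")
    return pair_dyad(a, b, melody_length)


class TestSignedAsynchronies:
    def test_identity_is_zero(self):
        r = np.arange(10) * 450.0
        assert np.allclose(signed_asynchronies(r, r), 0.0)

    def test_constant_offsets(self):
        r = np.arange(10) * 450.0
        assert np.allclose(signed_asynchronies(r + 10.0, r), 10.0)

    def test_anticipation_is_negative(self):
        # tapping 39.1 ms ahead of the cue gives a mean of −39.1 ms,
        # the sign convention of the reported negative mean asynchrony
        r = np.arange(72) * 450.0
        asyn = signed_asynchronies(r - 39.1, r)
        assert np.isclose(asyn.mean(), -39.1)

    def test_length_mismatch(self):
        with pytest.raises(DyadSyncError, match="mismatch"):
            signed_asynchronies([0.0, 1.0], [0.0])


class TestTrialSummary:
    def test_constant_iti_zero_asynchrony(self):
        onsets = np.arange(72) * 450.0
        sched = StimulusSchedule(450.0, 8, np.arange(76) * 450.0)
        s = trial_summary(_trial(onsets, task="solo_normal"), sched)
        assert s.mean_iti_ms == pytest.approx(450.0)
        assert s.sd_signed_asynchrony_ms == pytest.approx(0.0)
        assert s.mean_signed_asynchrony_ms == pytest.approx(0.0)

    def test_solo_alignment_ignores_whole_period_clock_offset(self):
        # trial clock shifted by exactly one period: asynchrony unchanged
        sched = StimulusSchedule(450.0, 8, np.arange(76) * 450.0)
        s = trial_summary(_trial(np.arange(72) * 450.0 + 450.0 - 20.0,
                                 task="solo_normal"), sched)
        assert s.mean_signed_asynchrony_ms == pytest.approx(-20.0)

    def test_injected_gaussian_sd_recovered(self, rng):
        # Monte-Carlo: sd of signed asynchronies ≈ injected 20 ms
        n = 4000
        noise = rng.normal(0.0, 20.0, n)
        base = np.arange(n) * 450.0
        sched = StimulusSchedule(450.0, 8, base)
        # trial clock offset by two whole periods; alignment must absorb it
        trial = _trial(np.sort(base + 900.0 + noise), task="solo_normal")
        s = trial_summary(trial, sched)
        assert s.sd_signed_asynchrony_ms == pytest.approx(20.0, rel=0.05)

    def test_dyad_constant_lead(self):
        s = trial_summary(_dyad(np.full(72, -5.0)))
        assert s.mean_absolute_asynchrony_ms == pytest.approx(5.0)
        assert s.sd_signed_asynchrony_ms == pytest.approx(0.0)
        assert s.mean_signed_asynchrony_ms == pytest.approx(-5.0)

    def test_solo_requires_schedule(self):
        with pytest.raises(DyadSyncError, match="[Ss]chedule"):
            trial_summary(_trial(np.arange(72) * 450.0, task="solo_normal"))

    def test_nominal_grid_reference_flag(self):
        onsets = np.arange(76) * 450.0
        onsets[2] += 40.0
        sched = StimulusSchedule(450.0, 8, onsets, delays_ms={2: 40.0})
        produced = _trial(np.arange(72) * 450.0, task="solo_delay")
        vs_sounded = trial_summary(produced, sched)
        vs_grid = trial_summary(produced, sched, use_nominal_grid=True)
        assert vs_grid.mean_signed_asynchrony_ms == pytest.approx(0.0)
        assert vs_sounded.mean_signed_asynchrony_ms == pytest.approx(-40.0 / 72)


class TestAsynchronyProfile:
    def test_constant(self):
        p = asynchrony_profile(_dyad(np.full(72, 7.5)))
        assert np.allclose(p.values_ms, 7.5)
        assert p.n_repetitions_averaged == 9
        assert p.initial_asynchrony_ms == pytest.approx(7.5)

    def test_single_position_bump(self):
        asyn = np.zeros(72)
        asyn[0::8] = 10.0  # melody position 1 in every repetition
        p = asynchrony_profile(_dyad(asyn))
        assert np.allclose(p.values_ms, [10, 0, 0, 0, 0, 0, 0, 0])

    def test_matches_bruteforce_position_means(self, rng):
        asyn = rng.normal(0.0, 30.0, 72)
        p = asynchrony_profile(_dyad(asyn))
        brute = [np.mean([asyn[i] for i in range(72) if i % 8 == pos])
                 for pos in range(8)]
        assert np.allclose(p.values_ms, brute)

    def test_incomplete_repetitions_rejected(self):
        with pytest.raises(DyadSyncError, match="divisible"):
            asynchrony_profile(_dyad(np.zeros(70)))

    @given(st.lists(st.floats(-200, 200), min_size=72, max_size=72))
    @settings(max_examples=30, deadline=None)
    def test_mean_abs_at_least_abs_mean(self, asyn):
        s = trial_summary(_dyad(asyn))
        assert s.mean_absolute_asynchrony_ms >= abs(s.mean_signed_asynchrony_ms) - 1e-9


class TestConditionSummaries:
    def _frame(self, entries):
        return summaries_frame(entries)

    def test_single_trial_cell_echoes_trial(self):
        d = _dyad(np.full(72, 4.0))
        df = condition_summaries(self._frame([(d, trial_summary(d))]))
        row = df[~df["empty_cell"]].iloc[0]
        assert row["mean_signed_asynchrony_ms_mean"] == pytest.approx(4.0)

    def test_two_identical_units_zero_se(self):
        d1 = _dyad(np.full(72, 4.0))
        d2 = pair_dyad(
            _trial(np.arange(72) * 450.0 + 1004.0, performer="A", pair="P02"),
            _trial(np.arange(72) * 450.0 + 1000.0, performer="B", pair="P02"),
        )
        df = condition_summaries(
            self._frame([(d, trial_summary(d)) for d in (d1, d2)])
        )
        row = df[~df["empty_cell"]].iloc[0]
        assert row["mean_signed_asynchrony_ms_se"] == pytest.approx(0.0)
        assert row["n_units"] == 2

    def test_empty_cells_flagged_not_dropped(self):
        d = _dyad(np.full(72, 4.0))
        df = condition_summaries(
            self._frame([(d, trial_summary(d))]),
            tasks=["joint_baseline", "joint_post_delay"],
        )
        empty = df[df["task"] == "joint_post_delay"]
        assert len(empty) == 1 and bool(empty["empty_cell"].iloc[0])

    def test_order_invariance(self, rng):
        dyads = [_dyad(rng.normal(0, 20, 72)) for _ in range(4)]
        entries = [(d, trial_summary(d)) for d in dyads]
        a = condition_summaries(self._frame(entries))
        b = condition_summaries(self._frame(entries[::-1]))
        pd.testing.assert_frame_equal(a, b, check_exact=False)

    def test_solo_vs_joint_classes(self):
        d = _dyad(np.full(72, 4.0))
        sched = StimulusSchedule(450.0, 8, np.arange(72) * 450.0)
        solo = _trial(np.arange(72) * 450.0 - 30.0 + 450.0, task="solo_normal")
        entries = [(d, trial_summary(d)), (solo, trial_summary(solo, sched))]
        tab = solo_vs_joint_table(self._frame(entries)).set_index("task_class")
        assert tab.loc["joint", "mean_absolute_asynchrony_ms"] == pytest.approx(4.0)
        assert tab.loc["solo", "mean_absolute_asynchrony_ms"] == pytest.approx(30.0)
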