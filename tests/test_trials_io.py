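"""Trial containers, validation rules, and CSV round-tripping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync.synth import GeneratorConfig, make_experiment
from dyadsync.trials import (
    CSV_COLUMNS,
    PairingError,
    SchemaError,
    ShortTrialError,
    StimulusSchedule,
    TapTrial,
    TrialValidationError,
    pair_dyad,
    read_trials,
    trim_trial,
    write_trials,
)


def _trial(n=76, task="joint_baseline", pair="P01", performer="A", trial=1,
           order="delay_first", start=0.0):
    return TapTrial(pair, performer, task, order, trial,
                    start + np.arange(n) * 450.0)


class TestTapTrialValidation:
    def test_well_formed(self):
        t = _trial()
        assert t.n_taps == 76
        assert np.allclose(t.intertap_intervals_ms, 450.0)

    @pytest.mark.parametrize(
        "onsets, message",
        [
            ([100.0, 50.0, 200.0], "increasing"),
            ([-5.0, 100.0], "negative"),
            ([100.0, 100.0], "increasing"),
            ([np.nan, 100.0], "finite"),
        ],
    )
    def test_invalid_onsets_rejected(self, onsets, message):
        with pytest.raises(TrialValidationError, match=message):
            TapTrial("P01", "A", "solo_normal", "delay_first", 1, np.array(onsets))

    def test_unknown_labels_rejected(self):
        with pytest.raises(TrialValidationError):
            TapTrial("P01", "A", "warmup", "delay_first", 1, np.array([0.0, 450.0]))
        with pytest.raises(TrialValidationError):
            TapTrial("P01", "A", "solo_normal", "sideways", 1, np.array([0.0, 450.0]))

    @given(gaps=st.lists(st.floats(0.1, 900.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_any_strictly_increasing_sequence_accepted(self, gaps):
        onsets = np.cumsum(np.asarray(gaps))
        t = TapTrial("P", "A", "solo_normal", "delay_first", 1, onsets)
        assert t.n_taps == len(gaps)


class TestTrim:
    def test_76_to_72(self):
        trimmed = trim_trial(_trial(76))
        assert trimmed.n_taps == 72
        assert np.array_equal(trimmed.onsets_ms, _trial(76).onsets_ms[:72])

    def test_exactly_72_unchanged(self):
        t = _trial(72)
        assert trim_trial(t) is t

    def test_short_trial_error(self):
        with pytest.raises(ShortTrialError):
            trim_trial(_trial(70))


class TestPairing:
    def test_positions_cycle(self):
        d = pair_dyad(_trial(72, performer="A"), _trial(72, performer="B", start=5.0))
        pos = d.melody_positions
        assert len(d.paired_onsets) == 72
        assert list(pos[:9]) == [1, 2, 3, 4, 5, 6, 7, 8, 1]
        assert np.allclose(d.asynchronies_ms, -5.0)

    def test_different_pairs_rejected(self):
        with pytest.raises(PairingError, match="pair_id"):
            pair_dyad(_trial(72, pair="P01"), _trial(72, pair="P02", performer="B"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError, match="length"):
            pair_dyad(_trial(72), _trial(71, performer="B"))


class TestStimulusSchedule:
    def test_grid_and_delays(self):
        s = StimulusSchedule(450.0, 8, np.arange(10) * 450.0 + [0, 0, 40, 0, 0, 0, 0, 0, 0, 0],
                             delays_ms={2: 40.0})
        assert s.delayed_positions == frozenset({2})
        assert np.allclose(s.nominal_onsets_ms(), np.arange(10) * 450.0)

    @pytest.mark.parametrize("pos", [0, 9])
    def test_first_last_tone_never_delayed(self, pos):
        onsets = np.arange(10) * 450.0
        onsets[pos] += 40.0
        with pytest.raises(TrialValidationError):
            StimulusSchedule(450.0, 8, onsets, delays_ms={pos: 40.0})

    def test_onsets_must_match_declared_delays(self):
        with pytest.raises(TrialValidationError):
            StimulusSchedule(450.0, 8, np.arange(10) * 450.0, delays_ms={2: 40.0})


class TestCsvRoundTrip:
    def test_roundtrip_lossless(self, tmp_path):
        """A generated session written to CSV reads back identically."""
        exp = make_experiment(GeneratorConfig(n_pairs=1, seed=42))
        path = write_trials(exp.trials, tmp_path / "s.csv", metadata={"seed": 42})
        back = read_trials(path)
        assert len(back) == len(exp.trials)
        key = lambda t: (t.pair_id, t.performer_id, t.task, t.trial_index)
        for a, b in zip(sorted(exp.trials, key=key), sorted(back, key=key)):
            assert key(a) == key(b)
            assert a.order == b.order
            assert np.allclose(a.onsets_ms, b.onsets_ms, atol=1e-9)

    def test_missing_column_is_schema_error(self, tmp_path):
        df = pd.DataFrame({c: [] for c in CSV_COLUMNS[:-1]})
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="onset_ms"):
            read_trials(p)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        rows = [["P01", "A", "solo_normal", "delay_first", 1, i + 1, i * 450.0]
                for i in range(5)]
        rows[2][6] = ""  # missing onset on data line 4
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match=r"\[4\]"):
            read_trials(p)

    def test_shuffled_onset_column_is_validation_error(self, tmp_path):
        onsets = np.arange(76) * 450.0
        shuffled = onsets.copy()
        np.random.default_rng(0).shuffle(shuffled)
        df = pd.DataFrame(
            [["P01", "A", "solo_normal", "delay_first", 1, i + 1, o]
             for i, o in enumerate(shuffled)],
            columns=CSV_COLUMNS,
        )
        p = tmp_path / "shuffled.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TrialValidationError, match="increasing"):
            read_trials(p)

    def test_unsupported_schema_version(self, tmp_path):
        p = tmp_path / "x.csv"
        pd.DataFrame(columns=CSV_COLUMNS).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="version"):
            read_trials(p, schema_version="99")
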