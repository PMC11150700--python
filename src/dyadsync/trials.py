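"""Trial-level tap data: containers, validation, CSV round-trip.

The canonical interchange format is a UTF-8 CSV with header

    pair_id,performer_id,task,order,trial,tap_index,onset_ms

one row per tap, one file per session, with an optional sidecar JSON
(``<name>.meta.json``) holding session metadata (counterbalancing order,
generator seed for synthetic sessions, ...).  Onsets are ms floats from
trial start; the metronome lead-in is not stored, taps begin with the
continuation phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TASKS = (
    "solo_normal",
    "solo_delay",
    "joint_baseline",
    "joint_post_delay",
    "joint_post_normal",
)
SOLO_TASKS = ("solo_normal", "solo_delay")
JOINT_TASKS = ("joint_baseline", "joint_post_delay", "joint_post_normal")
ORDERS = ("delay_first", "normal_first")

#: taps produced per trial and taps retained for analysis
RAW_TAPS = 76
ANALYSIS_TAPS = 72

CSV_COLUMNS = [
    "pair_id", "performer_id", "task", "order", "trial", "tap_index", "onset_ms",
]

SCHEMA_VERSION = "1"


class DyadSyncError(Exception):
    """Base class for package errors."""


class SchemaError(DyadSyncError):
    """File does not match the documented CSV schema."""


class TrialValidationError(DyadSyncError):
    """A trial violates an invariant (non-monotone onsets, bad labels...)."""


class ShortTrialError(DyadSyncError):
    """Trial has fewer taps than the analysis window requires."""


class PairingError(DyadSyncError):
    """Two trials cannot be paired into a dyad."""


@dataclass(frozen=True)
class TapTrial:
    """One performer's tap-onset sequence for one trial."""

    pair_id: str
    performer_id: str  # "A" = lower melody, "B" = higher melody
    task: str
    order: str
    trial_index: int
    onsets_ms: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_ms, dtype=float)
        object.__setattr__(self, "onsets_ms", onsets)
        if self.task not in TASKS:
            raise TrialValidationError(f"unknown task {self.task!r} in {self.label}")
        if self.order not in ORDERS:
            raise TrialValidationError(f"unknown order {self.order!r} in {self.label}")
        if self.trial_index < 1:
            raise TrialValidationError(f"trial_index must be >= 1 in {self.label}")
        if onsets.ndim != 1 or onsets.size == 0:
            raise TrialValidationError(f"empty onset sequence in {self.label}")
        if not np.all(np.isfinite(onsets)):
            raise TrialValidationError(f"non-finite onsets in {self.label}")
        if np.any(onsets < 0):
            raise TrialValidationError(f"negative onsets in {self.label}")
        if np.any(np.diff(onsets) <= 0):
            raise TrialValidationError(
                f"onsets not strictly increasing in {self.label}"
            )

    @property
    def label(self) -> str:
        return (
            f"trial(pair={self.pair_id}, performer={self.performer_id}, "
            f"task={self.task}, trial={self.trial_index})"
        )

    @property
    def n_taps(self) -> int:
        return int(self.onsets_ms.size)

    @property
    def intertap_intervals_ms(self) -> np.ndarray:
        return np.diff(self.onsets_ms)


@dataclass(frozen=True)
class StimulusSchedule:
    """Planned tone onsets of a computer-generated recording.

    Undelayed tones fall on the nominal period grid; tones listed in
    ``delays_ms`` are shifted late by the given amount (the following tones
    stay on the grid — delays are local).
    """

    nominal_period_ms: float
    melody_length: int
    tone_onsets_ms: np.ndarray
    delays_ms: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.tone_onsets_ms, dtype=float)
        object.__setattr__(self, "tone_onsets_ms", onsets)
        object.__setattr__(self, "delays_ms", dict(self.delays_ms))
        n = onsets.size
        if n == 0:
            raise TrialValidationError("empty stimulus schedule")
        grid = np.arange(n) * self.nominal_period_ms
        expected = grid.copy()
        for pos, d in self.delays_ms.items():
            if pos in (0, n - 1):
                raise TrialValidationError(
                    "first and last tones of a trial may not be delayed"
                )
            expected[pos] += d
        if not np.allclose(onsets, expected, atol=1e-9):
            raise TrialValidationError(
                "tone onsets inconsistent with grid + declared delays"
            )

    @property
    def n_tones(self) -> int:
        return int(self.tone_onsets_ms.size)

    @property
    def delayed_positions(self) -> frozenset:
        return frozenset(self.delays_ms)

    @property
    def n_repetitions(self) -> float:
        return self.n_tones / self.melody_length

    def nominal_onsets_ms(self) -> np.ndarray:
        """The undelayed grid (for sensitivity checks)."""
        return np.arange(self.n_tones) * self.nominal_period_ms


@dataclass(frozen=True)
class DyadTrial:
    """Two partners' trimmed trials paired tap-by-tap."""

    trial_a: TapTrial
    trial_b: TapTrial
    melody_length: int = 8

    def __post_init__(self) -> None:
        a, b = self.trial_a, self.trial_b
        for attr in ("pair_id", "task", "order", "trial_index"):
            if getattr(a, attr) != getattr(b, attr):
                raise PairingError(
                    f"cannot pair trials differing in {attr}: "
                    f"{a.label} vs {b.label}"
                )
        if a.n_taps != b.n_taps:
            raise PairingError(
                f"length mismatch ({a.n_taps} vs {b.n_taps}) pairing {a.label}"
            )

    @property
    def n_taps(self) -> int:
        return self.trial_a.n_taps

    @property
    def melody_positions(self) -> np.ndarray:
        """Melody position of tap n: cycles 1..melody_length."""
        return np.arange(self.n_taps) % self.melody_length + 1

    @property
    def paired_onsets(self) -> list[tuple[float, float, int]]:
        pos = self.melody_positions
        return [
            (float(a), float(b), int(p))
            for a, b, p in zip(
                self.trial_a.onsets_ms, self.trial_b.onsets_ms, pos
            )
        ]

    @property
    def asynchronies_ms(self) -> np.ndarray:
        """Signed asynchrony per tap: partner A onset minus partner B onset."""
        return self.trial_a.onsets_ms - self.trial_b.onsets_ms


def trim_trial(trial: TapTrial, n_taps: int = ANALYSIS_TAPS) -> TapTrial:
    """Keep the first ``n_taps`` onsets (the analysis window).

    Raw trials carry 76 taps; the final 4 are dropped so that exactly 9
    full melody repetitions (72 taps) remain.
    """
    if trial.n_taps < n_taps:
        raise ShortTrialError(
            f"{trial.label} has {trial.n_taps} taps, need >= {n_taps}"
        )
    if trial.n_taps == n_taps:
        return trial
    return replace(trial, onsets_ms=trial.onsets_ms[:n_taps])


def pair_dyad(trial_a: TapTrial, trial_b: TapTrial, melody_length: int = 8) -> DyadTrial:
    """Pair two performers' trials tap-by-tap (ordinal pairing).

    The task design yields one tap per tone position, so tap n of A is
    matched with tap n of B; melody position is ((n−1) mod 8) + 1.
    """
    return DyadTrial(trial_a, trial_b, melody_length)


def read_trials(path: str | Path, schema_version: str = SCHEMA_VERSION) -> list[TapTrial]:
    """Read a session CSV into TapTrial objects.

    Malformed rows are reported with their line numbers; non-monotone
    onsets raise a validation error naming the offending trial.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = df[CSV_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"{path}: malformed rows at lines {lines[:20]}")

    trials = []
    keys = ["pair_id", "performer_id", "task", "order", "trial"]
    for (pair, perf, task, order, idx), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("tap_index")
        tap_idx = grp["tap_index"].to_numpy()
        if np.any(np.diff(tap_idx) != 1):
            raise TrialValidationError(
                f"non-contiguous tap_index in trial (pair={pair}, "
                f"performer={perf}, task={task}, trial={idx})"
            )
        trials.append(
            TapTrial(
                pair_id=str(pair),
                performer_id=str(perf),
                task=str(task),
                order=str(order),
                trial_index=int(idx),
                onsets_ms=grp["onset_ms"].to_numpy(dtype=float),
            )
        )
    return trials


def trials_to_frame(trials: Iterable[TapTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for i, onset in enumerate(t.onsets_ms, start=1):
            rows.append(
                (t.pair_id, t.performer_id, t.task, t.order, t.trial_index, i, onset)
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_trials(
    trials: Sequence[TapTrial],
    path: str | Path,
    metadata: Mapping | None = None,
) -> Path:
    """Write trials to the canonical CSV (plus optional sidecar JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials_to_frame(trials).to_csv(path, index=False)
    if metadata is not None:
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return path


def read_metadata(path: str | Path) -> dict:
    sidecar = Path(path).with_suffix(".meta.json")
    return json.loads(sidecar.read_text())
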