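"""Behavioral synchronization measures for solo and joint tapping trials.

Sign convention: asynchrony = produced onset − reference onset, so
anticipation (tapping ahead of the cue or the partner) is negative.  For
solo trials the reference is the stimulus tone actually sounded (including
any feedback delays); a flag allows referencing the underlying regular
grid instead.  For joint trials the asynchrony is partner A's onset minus
partner B's onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trials import (
    DyadTrial,
    DyadSyncError,
    JOINT_TASKS,
    SOLO_TASKS,
    StimulusSchedule,
    TapTrial,
)


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial synchronization statistics over the analyzed taps."""

    mean_signed_asynchrony_ms: float
    mean_absolute_asynchrony_ms: float
    sd_signed_asynchrony_ms: float
    mean_iti_ms: float

    def __post_init__(self) -> None:
        assert self.mean_absolute_asynchrony_ms >= abs(self.mean_signed_asynchrony_ms) - 1e-9
        assert self.sd_signed_asynchrony_ms >= 0


@dataclass(frozen=True)
class AsynchronyProfile:
    """Per-melody-position mean signed asynchronies for one joint trial.

    ``values_ms[p]`` is the mean over the trial's repetitions of the
    asynchrony (A − B) at melody position p+1.  ``initial_asynchrony_ms``
    records the first paired tap's asynchrony; the fitting pipeline uses it
    as the model's initial condition.
    """

    trial_ref: str
    values_ms: np.ndarray
    n_repetitions_averaged: int
    initial_asynchrony_ms: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values_ms", np.asarray(self.values_ms, dtype=float))
        if self.values_ms.ndim != 1:
            raise DyadSyncError("profile values must be one-dimensional")

    @property
    def melody_length(self) -> int:
        return int(self.values_ms.size)


def signed_asynchronies(
    produced: Sequence[float], reference: Sequence[float]
) -> np.ndarray:
    """Element-wise produced − reference (ms); negative = anticipation."""
    produced = np.asarray(produced, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if produced.shape != reference.shape:
        raise DyadSyncError(
            f"length mismatch: {produced.size} produced vs {reference.size} reference"
        )
    return produced - reference


def _summary_from_asynchronies(asyn: np.ndarray, onsets: np.ndarray) -> TrialSummary:
    return TrialSummary(
        mean_signed_asynchrony_ms=float(np.mean(asyn)),
        mean_absolute_asynchrony_ms=float(np.mean(np.abs(asyn))),
        sd_signed_asynchrony_ms=float(np.std(asyn, ddof=1)) if asyn.size > 1 else 0.0,
        mean_iti_ms=float(np.mean(np.diff(onsets))),
    )


def trial_summary(
    trial: TapTrial | DyadTrial,
    reference: StimulusSchedule | None = None,
    use_nominal_grid: bool = False,
) -> TrialSummary:
    """All four statistics for one trial.

    For a solo :class:`TapTrial` a :class:`StimulusSchedule` reference is
    required; for a :class:`DyadTrial` the partner is the reference.
    """
    if isinstance(trial, DyadTrial):
        asyn = trial.asynchronies_ms
        return _summary_from_asynchronies(asyn, trial.trial_a.onsets_ms)
    if reference is None:
        raise DyadSyncError("solo trials need a StimulusSchedule reference")
    n = trial.n_taps
    if reference.n_tones < n:
        raise DyadSyncError(
            f"schedule has {reference.n_tones} tones but trial has {n} taps"
        )
    ref = (
        reference.nominal_onsets_ms() if use_nominal_grid else reference.tone_onsets_ms
    )[:n]
    # produced onsets are on the trial clock whose origin may differ from the
    # schedule clock by a whole number of periods; align by the first tone
    offset = round((trial.onsets_ms[0] - ref[0]) / reference.nominal_period_ms)
    asyn = signed_asynchronies(trial.onsets_ms, ref + offset * reference.nominal_period_ms)
    return _summary_from_asynchronies(asyn, trial.onsets_ms)


def asynchrony_profile(dyad: DyadTrial) -> AsynchronyProfile:
    """Mean signed asynchrony (A − B) per melody position.

    Requires complete repetitions (n_taps divisible by the melody length).
    """
    L = dyad.melody_length
    n = dyad.n_taps
    if n % L != 0:
        raise DyadSyncError(
            f"incomplete repetitions: {n} taps not divisible by melody length {L}"
        )
    asyn = dyad.asynchronies_ms
    values = asyn.reshape(n // L, L).mean(axis=0)
    ref = (
        f"{dyad.trial_a.pair_id}:{dyad.trial_a.task}:"
        f"{dyad.trial_a.order}:{dyad.trial_a.trial_index}"
    )
    return AsynchronyProfile(
        trial_ref=ref,
        values_ms=values,
        n_repetitions_averaged=n // L,
        initial_asynchrony_ms=float(asyn[0]),
    )


STAT_COLUMNS = [
    "mean_signed_asynchrony_ms",
    "mean_absolute_asynchrony_ms",
    "sd_signed_asynchrony_ms",
    "mean_iti_ms",
]


def summaries_frame(
    entries: Iterable[tuple[TapTrial | DyadTrial, TrialSummary]]
) -> pd.DataFrame:
    """Tabulate (trial, summary) pairs with identifying columns."""
    rows = []
    for trial, summ in entries:
        base = trial.trial_a if isinstance(trial, DyadTrial) else trial
        unit = (
            base.pair_id
            if isinstance(trial, DyadTrial)
            else f"{base.pair_id}:{base.performer_id}"
        )
        rows.append(
            {
                "pair_id": base.pair_id,
                "unit": unit,
                "task": base.task,
                "order": base.order,
                "trial": base.trial_index,
                **{c: getattr(summ, c) for c in STAT_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


def condition_summaries(
    summaries: pd.DataFrame,
    tasks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per task × order cell means and standard errors of each statistic.

    Aggregation follows the design's random-effect units: statistics are
    first averaged within unit (participant for solo tasks, pair for joint
    tasks) across that unit's trials, then averaged across units; the SE is
    across units.  Cells with no data are kept with n_units = 0 and NaN
    statistics rather than silently dropped.
    """
    if summaries.empty:
        raise DyadSyncError("no trial summaries to aggregate")
    out = []
    want_tasks = list(tasks) if tasks is not None else sorted(summaries["task"].unique())
    orders = sorted(summaries["order"].unique())
    for task in want_tasks:
        for order in orders:
            cell = summaries[(summaries["task"] == task) & (summaries["order"] == order)]
            row: dict = {"task": task, "order": order, "n_units": cell["unit"].nunique()}
            if cell.empty:
                for c in STAT_COLUMNS:
                    row[f"{c}_mean"] = np.nan
                    row[f"{c}_se"] = np.nan
                row["empty_cell"] = True
            else:
                per_unit = cell.groupby("unit")[STAT_COLUMNS].mean()
                for c in STAT_COLUMNS:
                    row[f"{c}_mean"] = float(per_unit[c].mean())
                    row[f"{c}_se"] = (
                        float(per_unit[c].std(ddof=1) / np.sqrt(len(per_unit)))
                        if len(per_unit) > 1
                        else 0.0
                    )
                row["empty_cell"] = False
            out.append(row)
    return pd.DataFrame(out)


def solo_vs_joint_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute asynchrony by task class (solo vs joint), per pair.

    Mirrors the comparison of synchrony with a regular recording
    (unidirectional coupling) against synchrony with a partner
    (bidirectional coupling).
    """
    df = summaries.copy()
    df["task_class"] = np.where(df["task"].isin(SOLO_TASKS), "solo", "joint")
    per_pair = (
        df.groupby(["pair_id", "task_class"])["mean_absolute_asynchrony_ms"]
        .mean()
        .unstack("task_class")
    )
    res = per_pair.agg(["mean", "sem"]).T
    res.columns = ["mean_absolute_asynchrony_ms", "se"]
    res.index.name = "task_class"
    return res.reset_index()
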