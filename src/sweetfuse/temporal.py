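"""Cohort curves and the anchored sweet-period search.

A cohort curve stacks one statistic per frame time over all trials:
either the proportion of trials whose frame at that time is valid, or
the classification accuracy among the frames that are valid (vision) or
present (sEMG) there.  Curve points keep their numerator/denominator
counts, and a point with an empty denominator is carried as an explicit
NaN — never imputed, never zero.

The sweet period is the highest-scoring window [0, e) by mean valid
proportion among windows of at least ``min_window_frames`` frames; the
anchor at 0 ms reflects the goal of classifying as early in the reach as
possible.  Very short windows can score highest yet rest on too few
frames to vote reliably, hence the minimum-length constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import NO_PREDICTION, TrialStream, frames_in_window, TimelineSpec

__all__ = [
    "CohortCurve",
    "SweetPeriod",
    "valid_proportion_curve",
    "accuracy_curve",
    "anchored_window_scores",
    "find_sweet_period",
    "window_mean_accuracy",
    "SOURCES",
]

SOURCES = ("gesture_vision", "object_vision", "emg")


@dataclass
class CohortCurve:
    """A per-timepoint statistic with its counting basis."""

    name: str
    times: np.ndarray        # ms, one per decision time
    numerator: np.ndarray    # int counts
    denominator: np.ndarray  # int counts; 0 marks an undefined point

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.numerator = np.asarray(self.numerator, dtype=np.int64)
        self.denominator = np.asarray(self.denominator, dtype=np.int64)
        if not (len(self.times) == len(self.numerator) == len(self.denominator)):
            raise ValueError("curve arrays must share one length")
        if np.any(self.numerator > self.denominator) or np.any(self.numerator < 0):
            raise ValueError("numerators must lie in [0, denominator]")

    @property
    def values(self) -> np.ndarray:
        """Proportions, NaN where the denominator is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.numerator / self.denominator
        return np.where(self.denominator > 0, v, np.nan)

    @property
    def defined(self) -> np.ndarray:
        return self.denominator > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": self.name,
                "time_ms": self.times,
                "value": self.values,
                "numerator": self.numerator,
                "denominator": self.denominator,
            }
        )


@dataclass(frozen=True)
class SweetPeriod:
    """An anchored window [0, end) selected by the validity search."""

    start: int
    end: int
    score: float
    frame_count: int

    def __post_init__(self) -> None:
        if self.start != 0:
            raise ValueError("sweet periods are anchored at 0 ms")
        if self.frame_count < 1:
            raise ValueError("sweet period must contain at least one frame")


def _frame_matrix(cohort: Sequence[TrialStream], attr: str) -> np.ndarray:
    if not cohort:
        raise ValueError("empty cohort")
    return np.vstack([getattr(t, attr) for t in cohort])


def valid_proportion_curve(cohort: Sequence[TrialStream]) -> CohortCurve:
    """Share of trials whose frame at each time point is valid."""
    valid = _frame_matrix(cohort, "frame_valid")
    n = len(cohort)
    return CohortCurve(
        name="valid_proportion",
        times=cohort[0].frame_time,
        numerator=valid.sum(axis=0),
        denominator=np.full(valid.shape[1], n, dtype=np.int64),
    )


def accuracy_curve(cohort: Sequence[TrialStream], source: str) -> CohortCurve:
    """Per-timepoint classification accuracy for one decision source.

    Vision sources condition on frame validity (the classifier only ran
    on valid frames); the sEMG source counts every decision point.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}; expected one of {SOURCES}")
    if not cohort:
        raise ValueError("empty cohort")

    if source == "emg":
        times = cohort[0].emg_time
        for t in cohort:
            if not np.array_equal(t.emg_time, times):
                raise ValueError("trials disagree on sEMG decision times")
        pred = np.vstack([t.emg_predicted_gesture for t in cohort])
        truth = np.array([t.true_gesture for t in cohort])[:, None]
        correct = pred == truth
        n = len(cohort)
        return CohortCurve(
            name="emg_accuracy",
            times=times,
            numerator=correct.sum(axis=0),
            denominator=np.full(len(times), n, dtype=np.int64),
        )

    valid = _frame_matrix(cohort, "frame_valid")
    if source == "gesture_vision":
        pred = _frame_matrix(cohort, "predicted_gesture")
        truth = np.array([t.true_gesture for t in cohort])[:, None]
        correct = (pred == truth) & valid
    else:  # object_vision
        correct = np.vstack(
            [
                np.array(
                    [o == t.key.object for o in t.predicted_object], dtype=bool
                )
                for t in cohort
            ]
        ) & valid
    return CohortCurve(
        name=f"{source}_accuracy",
        times=cohort[0].frame_time,
        numerator=correct.sum(axis=0),
        denominator=valid.sum(axis=0),
    )


def anchored_window_scores(curve: CohortCurve) -> pd.DataFrame:
    """Mean curve value of every anchored window [0, e), one row per window.

    Undefined curve points (zero denominator) are excluded from a
    window's mean; a window containing only undefined points scores NaN.
    """
    frame_period = int(curve.times[1] - curve.times[0]) if len(curve.times) > 1 else 1
    vals = curve.values
    defined = curve.defined.astype(float)
    cum_vals = np.cumsum(np.where(curve.defined, vals, 0.0))
    cum_def = np.cumsum(defined)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(cum_def > 0, cum_vals / cum_def, np.nan)
    ends = curve.times + frame_period
    return pd.DataFrame(
        {
            "start_ms": 0,
            "end_ms": ends,
            "frame_count": np.arange(1, len(vals) + 1),
            "score": scores,
        }
    )


def find_sweet_period(curve: CohortCurve, min_window_frames: int = 5) -> SweetPeriod:
    """Best anchored window with at least ``min_window_frames`` frames.

    Ties are broken toward the shorter window, so a flat curve returns
    the minimal admissible window.
    """
    if min_window_frames < 1:
        raise ValueError("min_window_frames must be >= 1")
    if min_window_frames > len(curve.times):
        raise ValueError(
            f"min_window_frames={min_window_frames} exceeds the "
            f"{len(curve.times)}-frame trial"
        )
    table = anchored_window_scores(curve)
    admissible = table[table["frame_count"] >= min_window_frames]
    scores = admissible["score"].to_numpy()
    if np.all(np.isnan(scores)):
        raise ValueError("no admissible window has any defined curve point")
    best = int(np.nanargmax(scores))  # first maximum = shortest window
    row = admissible.iloc[best]
    return SweetPeriod(
        start=0,
        end=int(row["end_ms"]),
        score=float(row["score"]),
        frame_count=int(row["frame_count"]),
    )


def window_mean_accuracy(
    cohort: Sequence[TrialStream],
    source: str,
    window: tuple[int, int],
    spec: TimelineSpec | None = None,
) -> float:
    """Pooled accuracy over all decisions falling inside ``window``.

    Pools (trial, frame) pairs that are valid (vision) or present (sEMG);
    returns NaN when the window contains no usable decision in the whole
    cohort.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}; expected one of {SOURCES}")
    start, end = window
    correct = 0
    total = 0
    for trial in cohort:
        if source == "emg":
            in_win = (trial.emg_time >= start) & (trial.emg_time < end)
            votes = trial.emg_predicted_gesture[in_win]
            correct += int(np.sum(votes == trial.true_gesture))
            total += int(in_win.sum())
        else:
            in_win = (trial.frame_time >= start) & (trial.frame_time < end)
            use = in_win & trial.frame_valid
            if source == "gesture_vision":
                correct += int(
                    np.sum(trial.predicted_gesture[use] == trial.true_gesture)
                )
            else:
                correct += sum(
                    1 for o in trial.predicted_object[use] if o == trial.key.object
                )
            total += int(use.sum())
    if total == 0:
        return float("nan")
    return correct / total
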