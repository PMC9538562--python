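"""Leave-one-repetition-out evaluation and the end-to-end experiment driver.

Every (subject, gesture, object) condition is executed four times; fold
``r`` tests all trials of repetition ``r`` and uses the remaining
repetitions for sweet-period selection, mirroring a train/test split
even though nothing is fitted here.  Pooled accuracy counts each trial
exactly once across folds.

``vision_only`` accuracy is reported with two denominators, since the
choice is consequential whenever vision abstains: among trials with a
present vision decision (the primary figure), and over all trials with
abstentions counted as errors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GraspTaxonomy, TrialStream
from .fusion import FusionOutcome, fuse_trial
from .stream_io import ExperimentConfig, cohort_to_table, write_cohort
from .synthetic import GeneratorParams, generate_cohort
from .temporal import (
    CohortCurve,
    SweetPeriod,
    accuracy_curve,
    anchored_window_scores,
    find_sweet_period,
    valid_proportion_curve,
)

__all__ = [
    "FoldResult",
    "ExperimentReport",
    "loro_folds",
    "evaluate_fold",
    "run_experiment",
]

log = logging.getLogger(__name__)


def loro_folds(
    cohort: Sequence[TrialStream], n_repetitions: int = 4
) -> list[tuple[list[TrialStream], list[TrialStream]]]:
    """Leave-one-repetition-out partitions: fold r tests repetition r.

    Requires every (subject, gesture, object) condition to carry the
    full repetition set 1..n_repetitions.
    """
    expected = set(range(1, n_repetitions + 1))
    by_condition: dict[tuple, set[int]] = {}
    for t in cohort:
        cond = (t.key.subject, t.key.gesture, t.key.object)
        by_condition.setdefault(cond, set()).add(t.key.repetition)
    for cond, reps in by_condition.items():
        if reps != expected:
            raise ValueError(
                f"condition {cond} has repetitions {sorted(reps)}, "
                f"expected {sorted(expected)}"
            )
    folds = []
    for r in range(1, n_repetitions + 1):
        test = [t for t in cohort if t.key.repetition == r]
        train = [t for t in cohort if t.key.repetition != r]
        folds.append((train, test))
    return folds


@dataclass
class FoldResult:
    """Accuracies of one test fold under the three classification bases."""

    repetition: int
    n_trials: int
    n_vision_present: int
    emg_correct: int
    vision_correct: int
    integrated_correct: int
    emg_only: float
    vision_only: float        # among trials with a present vision decision
    vision_only_all: float    # abstentions counted as errors
    integrated: float
    sweet_period: SweetPeriod
    outcomes: list[FusionOutcome] = field(repr=False, default_factory=list)


@dataclass
class ExperimentReport:
    """Per-fold and pooled accuracies plus the provenance to rerun them."""

    seed: int
    config: ExperimentConfig
    folds: list[FoldResult]
    pooled_emg_only: float
    pooled_vision_only: float
    pooled_vision_only_all: float
    pooled_integrated: float
    n_trials: int

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "n_trials": self.n_trials,
            "pooled": {
                "emg_only": self.pooled_emg_only,
                "vision_only": self.pooled_vision_only,
                "vision_only_all": self.pooled_vision_only_all,
                "integrated": self.pooled_integrated,
            },
            "folds": [
                {
                    "repetition": f.repetition,
                    "n_trials": f.n_trials,
                    "n_vision_present": f.n_vision_present,
                    "emg_only": f.emg_only,
                    "vision_only": f.vision_only,
                    "vision_only_all": f.vision_only_all,
                    "integrated": f.integrated,
                    "sweet_period": dataclasses.asdict(f.sweet_period),
                }
                for f in self.folds
            ],
        }
        return d


def evaluate_fold(
    test_trials: Sequence[TrialStream],
    vision_window: SweetPeriod | tuple[int, int],
    emg_window: tuple[int, int],
) -> FoldResult:
    """Score one test fold under sEMG-only, vision-only and integration."""
    if not test_trials:
        raise ValueError("empty test fold")
    outcomes = [fuse_trial(t, vision_window, emg_window) for t in test_trials]

    n = len(outcomes)
    emg_correct = sum(o.emg.label == t.true_gesture
                      for o, t in zip(outcomes, test_trials))
    present = [(o, t) for o, t in zip(outcomes, test_trials) if o.vision.present]
    vis_correct = sum(o.vision.label == t.true_gesture for o, t in present)
    int_correct = sum(o.correct for o in outcomes)

    if isinstance(vision_window, SweetPeriod):
        sweet = vision_window
    else:
        start, end = vision_window
        period = int(test_trials[0].frame_time[1] - test_trials[0].frame_time[0])
        sweet = SweetPeriod(start=start, end=end, score=float("nan"),
                            frame_count=(end - start) // period)
    reps = {t.key.repetition for t in test_trials}
    return FoldResult(
        repetition=reps.pop() if len(reps) == 1 else -1,
        n_trials=n,
        n_vision_present=len(present),
        emg_correct=int(emg_correct),
        vision_correct=int(vis_correct),
        integrated_correct=int(int_correct),
        emg_only=emg_correct / n,
        vision_only=vis_correct / len(present) if present else float("nan"),
        vision_only_all=vis_correct / n,
        integrated=int_correct / n,
        sweet_period=sweet,
        outcomes=outcomes,
    )


def _outcomes_table(folds: Sequence[FoldResult]) -> pd.DataFrame:
    rows = []
    for f in folds:
        for o in f.outcomes:
            rows.append(
                {
                    "subject": o.key.subject,
                    "gesture": o.key.gesture,
                    "object": o.key.object,
                    "repetition": o.key.repetition,
                    "vision_label": o.vision.label if o.vision.present else "",
                    "vision_confidence": o.vision.confidence,
                    "vision_votes": o.vision.votes_cast,
                    "emg_label": o.emg.label,
                    "emg_confidence": o.emg.confidence,
                    "emg_votes": o.emg.votes_cast,
                    "chosen_source": o.chosen_source,
                    "final_label": o.final_label,
                    "correct": o.correct,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["subject", "gesture", "object", "repetition"], kind="mergesort"
    ).reset_index(drop=True)


def run_experiment(
    config: ExperimentConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    cohort: Sequence[TrialStream] | None = None,
    taxonomy: GraspTaxonomy | None = None,
) -> ExperimentReport:
    """Simulate (or take) a cohort, select sweet periods, fuse, aggregate.

    ``seed`` overrides ``config.seed``.  With ``sweet_period_scope ==
    "train"`` (default) each fold's vision window is selected from its
    training repetitions only; ``"all"`` selects once from the whole
    cohort.  If ``out_dir`` is given, writes ``report.json``,
    ``curves.csv``, ``outcomes.csv`` and ``window_scores.csv``.
    """
    t0 = _time.perf_counter()
    seed = config.seed if seed is None else seed
    taxonomy = taxonomy or GraspTaxonomy.default()
    if cohort is None:
        params = GeneratorParams.from_config(config, taxonomy)
        cohort = generate_cohort(params, seed)
        log.info("generated %d trials in %.1fs", len(cohort), _time.perf_counter() - t0)
    cohort = sorted(cohort, key=lambda t: t.key)

    folds_in = loro_folds(cohort, n_repetitions=config.repetitions)
    emg_window = tuple(config.emg_window)

    if config.sweet_period_scope not in ("train", "all"):
        raise ValueError(
            f"sweet_period_scope must be 'train' or 'all', got "
            f"{config.sweet_period_scope!r}"
        )
    global_curve = valid_proportion_curve(cohort)
    global_scores = anchored_window_scores(global_curve)
    if config.sweet_period_scope == "all":
        shared_sweet = find_sweet_period(global_curve, config.min_window_frames)

    fold_results: list[FoldResult] = []
    for train, test in folds_in:
        if config.sweet_period_scope == "train":
            sweet = find_sweet_period(
                valid_proportion_curve(train), config.min_window_frames
            )
        else:
            sweet = shared_sweet
        result = evaluate_fold(test, sweet, emg_window)
        log.info(
            "fold rep=%d: sweet period [0, %d) ms score=%.4f; "
            "emg=%.4f vision=%.4f integrated=%.4f",
            result.repetition, sweet.end, sweet.score,
            result.emg_only, result.vision_only, result.integrated,
        )
        fold_results.append(result)

    n_total = sum(f.n_trials for f in fold_results)
    n_present = sum(f.n_vision_present for f in fold_results)
    emg_correct = sum(f.emg_correct for f in fold_results)
    vis_correct = sum(f.vision_correct for f in fold_results)
    int_correct = sum(f.integrated_correct for f in fold_results)

    report = ExperimentReport(
        seed=seed,
        config=config,
        folds=fold_results,
        pooled_emg_only=emg_correct / n_total,
        pooled_vision_only=vis_correct / n_present if n_present else float("nan"),
        pooled_vision_only_all=vis_correct / n_total,
        pooled_integrated=int_correct / n_total,
        n_trials=n_total,
    )
    log.info(
        "pooled over %d trials: emg=%.4f vision=%.4f integrated=%.4f (%.1fs)",
        n_total, report.pooled_emg_only, report.pooled_vision_only,
        report.pooled_integrated, _time.perf_counter() - t0,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )
        curves = pd.concat(
            [global_curve.to_frame()]
            + [accuracy_curve(cohort, s).to_frame()
               for s in ("gesture_vision", "object_vision", "emg")],
            ignore_index=True,
        )
        curves.to_csv(out / "curves.csv", index=False)
        global_scores.to_csv(out / "window_scores.csv", index=False)
        _outcomes_table(fold_results).to_csv(out / "outcomes.csv", index=False)
    return report
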