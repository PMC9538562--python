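"""Reading and writing cohort decision-stream files, configs and reports.

A cohort lives in one flat CSV with a ``source`` column so the vision
frame stream and the sEMG decision stream share a schema; real classifier
exports and synthetic cohorts flow through the same reader.  Missing
predictions are written as the explicit sentinel token ``none`` (never an
empty cell) so a silently truncated row cannot masquerade as an invalid
frame.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    NO_PREDICTION,
    GraspTaxonomy,
    TimelineSpec,
    TrialKey,
    TrialStream,
)

__all__ = [
    "COLUMNS",
    "SENTINEL",
    "CohortFormatError",
    "SchemaError",
    "StructuralError",
    "ConsistencyError",
    "ConfigError",
    "ExperimentConfig",
    "read_cohort",
    "write_cohort",
    "load_config",
]

log = logging.getLogger(__name__)

#: Column order of a cohort CSV.
COLUMNS = (
    "subject",
    "gesture",
    "object",
    "repetition",
    "source",
    "time_ms",
    "valid",
    "predicted_gesture",
    "predicted_object",
    "true_gesture",
)

#: Token written where a field does not apply (e.g. predictions of invalid frames).
SENTINEL = "none"


class CohortFormatError(ValueError):
    """Base class for cohort-file validation failures."""


class SchemaError(CohortFormatError):
    """Header, column or vocabulary mismatch."""


class StructuralError(CohortFormatError):
    """Wrong row counts or times for a trial."""


class ConsistencyError(CohortFormatError):
    """Row-level contradiction, e.g. a valid frame without a prediction."""


class ConfigError(ValueError):
    """Malformed experiment configuration."""


# --------------------------------------------------------------------------- #
# experiment configuration
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ExperimentConfig:
    """Every knob of the pipeline, with the study's values as defaults.

    Timing fields are milliseconds.  The validity-curve and accuracy
    defaults are the synthetic generator's calibrated operating point
    (see :mod:`sweetfuse.synthetic`); the windows and phase boundaries
    are the study constants.
    """

    # timeline
    frame_period: int = 40
    trial_duration: int = 4480
    phase_boundaries: tuple[int, int] = (1020, 1604)
    # sweet periods
    emg_window: tuple[int, int] = (1100, 1400)
    min_window_frames: int = 5
    sweet_period_scope: str = "train"      # "train" or "all"
    vision_only_denominator: str = "present"  # "present" or "all"
    # cohort dimensions
    subjects: int = 30
    repetitions: int = 4
    # validity curve (vision frame availability)
    validity_baseline: float = 0.47
    validity_peak: float = 0.58
    validity_peak_time: int = 160
    validity_decline_end: int = 1604
    validity_floor: float = 0.08
    time_jitter: int = 120
    # classifier operating points
    vision_gesture_accuracy: float = 0.92
    vision_object_accuracy: float = 0.97
    emg_trial_accuracy: float = 0.855
    emg_consistency: float = 0.90
    emg_period: int = 40
    # randomness
    seed: int = 0

    def timeline(self) -> TimelineSpec:
        return TimelineSpec(
            frame_period=self.frame_period,
            trial_duration=self.trial_duration,
            phase_boundaries=tuple(self.phase_boundaries),
        )

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)


_LIST_KEYS = {"phase_boundaries", "emg_window"}


def load_config(path: str | Path | None) -> ExperimentConfig:
    """Load a YAML key/value config; absent keys fall back to defaults.

    Unknown keys are an error — a typo must never silently revert a
    parameter to its default.  ``path=None`` returns pure defaults.
    The effective configuration is echoed to the log.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        raw = loaded

    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")

    kwargs = {}
    for key, value in raw.items():
        if key in _LIST_KEYS:
            if not (isinstance(value, (list, tuple)) and len(value) == 2):
                raise ConfigError(f"{key} must be a 2-element list, got {value!r}")
            value = (int(value[0]), int(value[1]))
        kwargs[key] = value
    try:
        config = ExperimentConfig(**kwargs)
    except TypeError as exc:  # wrong value type for a field
        raise ConfigError(str(exc)) from exc
    config.timeline()  # surface timeline invariant violations now
    log.info("effective configuration: %s", dataclasses.asdict(config))
    return config


# --------------------------------------------------------------------------- #
# cohort files
# --------------------------------------------------------------------------- #

def _trial_frame_rows(trial: TrialStream) -> pd.DataFrame:
    k = trial.key
    n = len(trial.frame_time)
    pg = np.where(
        trial.frame_valid, trial.predicted_gesture.astype(str), SENTINEL
    )
    po = np.array(
        [o if o is not None else SENTINEL for o in trial.predicted_object],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "subject": k.subject,
            "gesture": k.gesture,
            "object": k.object,
            "repetition": k.repetition,
            "source": "vision",
            "time_ms": trial.frame_time,
            "valid": np.where(trial.frame_valid, "true", "false"),
            "predicted_gesture": pg,
            "predicted_object": po,
            "true_gesture": trial.true_gesture,
        }
    )


def _trial_emg_rows(trial: TrialStream) -> pd.DataFrame:
    k = trial.key
    return pd.DataFrame(
        {
            "subject": k.subject,
            "gesture": k.gesture,
            "object": k.object,
            "repetition": k.repetition,
            "source": "emg",
            "time_ms": trial.emg_time,
            "valid": SENTINEL,
            "predicted_gesture": trial.emg_predicted_gesture.astype(str),
            "predicted_object": SENTINEL,
            "true_gesture": trial.true_gesture,
        }
    )


def cohort_to_table(cohort: Sequence[TrialStream]) -> pd.DataFrame:
    """Long-format table of a cohort in deterministic row order."""
    parts = []
    for trial in cohort:
        parts.append(_trial_frame_rows(trial))
        if len(trial.emg_time):
            parts.append(_trial_emg_rows(trial))
    if not parts:
        return pd.DataFrame(columns=list(COLUMNS))
    table = pd.concat(parts, ignore_index=True)
    table = table.sort_values(
        ["subject", "gesture", "object", "repetition", "source", "time_ms"],
        kind="mergesort",
    ).reset_index(drop=True)
    return table[list(COLUMNS)]


def write_cohort(cohort: Sequence[TrialStream], path: str | Path) -> None:
    """Write a cohort CSV; byte-identical output for identical cohorts."""
    cohort_to_table(cohort).to_csv(path, index=False, lineterminator="\n")


def _parse_int(value: str, row: int, col: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise SchemaError(f"row {row}: column {col!r} is not an integer: {value!r}")


def read_cohort(
    path: str | Path,
    spec: TimelineSpec | None = None,
    taxonomy: GraspTaxonomy | None = None,
) -> list[TrialStream]:
    """Read a cohort CSV back into validated :class:`TrialStream` objects.

    Validation errors carry the 1-based file row number (header = row 1)
    or the offending trial key.
    """
    spec = spec or TimelineSpec()
    taxonomy = taxonomy or GraspTaxonomy.default()

    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(table.columns) != COLUMNS:
        raise SchemaError(
            f"{path}: header {tuple(table.columns)} does not match {COLUMNS}"
        )
    if table.empty:
        return []
    rows = table.index.to_numpy() + 2  # 1-based file rows, after the header

    known_gestures = {str(g) for g in taxonomy.gestures}
    known_objects = set(taxonomy.objects)

    trials: list[TrialStream] = []
    grouped = table.groupby(
        ["subject", "gesture", "object", "repetition"], sort=True
    )
    for (subj, gest, obj, rep), part in grouped:
        first_row = int(rows[part.index[0]])
        key = TrialKey(
            subject=_parse_int(subj, first_row, "subject"),
            gesture=_parse_int(gest, first_row, "gesture"),
            object=obj,
            repetition=_parse_int(rep, first_row, "repetition"),
        )
        if str(key.gesture) not in known_gestures:
            raise SchemaError(f"row {first_row}: unknown gesture ID {gest!r}")
        if obj not in known_objects:
            raise SchemaError(f"row {first_row}: unknown object {obj!r}")

        true_set = set(part["true_gesture"])
        if len(true_set) != 1:
            raise ConsistencyError(f"trial {key}: conflicting true_gesture values")
        true_gesture = _parse_int(true_set.pop(), first_row, "true_gesture")

        vis = part[part["source"] == "vision"].sort_values("time_ms", key=lambda s: s.astype(int))
        emg = part[part["source"] == "emg"].sort_values("time_ms", key=lambda s: s.astype(int))
        bad_source = part[~part["source"].isin(["vision", "emg"])]
        if len(bad_source):
            raise SchemaError(
                f"row {int(rows[bad_source.index[0]])}: unknown source "
                f"{bad_source['source'].iloc[0]!r}"
            )
        if len(vis) != spec.n_frames:
            raise StructuralError(
                f"trial {key}: expected {spec.n_frames} vision rows, got {len(vis)}"
            )

        valid = np.zeros(spec.n_frames, dtype=bool)
        pred_g = np.full(spec.n_frames, NO_PREDICTION, dtype=np.int64)
        pred_o = np.full(spec.n_frames, None, dtype=object)
        times = np.zeros(spec.n_frames, dtype=np.int64)
        for i, (idx, r) in enumerate(vis.iterrows()):
            row_no = int(rows[idx])
            times[i] = _parse_int(r["time_ms"], row_no, "time_ms")
            if r["valid"] not in ("true", "false"):
                raise ConsistencyError(
                    f"row {row_no}: vision 'valid' must be true/false, got {r['valid']!r}"
                )
            v = r["valid"] == "true"
            valid[i] = v
            if v:
                if r["predicted_gesture"] == SENTINEL or r["predicted_object"] == SENTINEL:
                    raise ConsistencyError(
                        f"row {row_no}: valid frame without predictions (trial {key})"
                    )
                pred_g[i] = _parse_int(r["predicted_gesture"], row_no, "predicted_gesture")
                pred_o[i] = r["predicted_object"]
            else:
                if r["predicted_gesture"] != SENTINEL or r["predicted_object"] != SENTINEL:
                    raise ConsistencyError(
                        f"row {row_no}: invalid frame carrying predictions (trial {key})"
                    )
        if not np.array_equal(times, spec.frame_times):
            raise StructuralError(
                f"trial {key}: vision frame times do not match the timeline"
            )

        emg_times = np.array(
            [_parse_int(t, int(rows[i]), "time_ms") for i, t in emg["time_ms"].items()],
            dtype=np.int64,
        )
        emg_pred = np.array(
            [
                _parse_int(g, int(rows[i]), "predicted_gesture")
                for i, g in emg["predicted_gesture"].items()
            ],
            dtype=np.int64,
        )
        bad_emg = emg[emg["valid"] != SENTINEL]
        if len(bad_emg):
            raise ConsistencyError(
                f"row {int(rows[bad_emg.index[0]])}: sEMG rows carry no validity flag"
            )

        trial = TrialStream(
            key=key,
            true_gesture=true_gesture,
            frame_time=times,
            frame_valid=valid,
            predicted_gesture=pred_g,
            predicted_object=pred_o,
            emg_time=emg_times,
            emg_predicted_gesture=emg_pred,
        )
        trial.validate(spec)
        trials.append(trial)

    keys = [t.key for t in trials]
    if len(set(keys)) != len(keys):
        raise StructuralError(f"{path}: duplicate trial keys")
    return trials
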