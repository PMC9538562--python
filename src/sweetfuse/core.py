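"""Domain types and frame/phase arithmetic for reach-and-grasp decision streams.

A grasp trial is a fixed-length recording of one reach-and-grasp action:
an egocentric camera emits one classifier decision per video frame (25 Hz
by default), and an sEMG classifier emits a parallel stream of gesture
votes.  Everything downstream — validity curves, sweet-period search,
plurality-vote fusion — is arithmetic over these streams, so the timeline
conventions live here and nowhere else.

Windows and phases are half-open intervals ``[start, end)`` measured in
milliseconds from the start of the reach; a frame "lives" at its start
time, so frame ``k`` sits at ``k * frame_period`` ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "PHASES",
    "NO_PREDICTION",
    "TimelineSpec",
    "GraspTaxonomy",
    "TrialKey",
    "FrameRecord",
    "EmgRecord",
    "TrialStream",
    "frames_in_window",
    "phase_of",
    "cohort_size",
]

#: Names of the three grasp phases, in temporal order.
PHASES = ("reaching", "early_grasping", "firm_grasping")

#: Sentinel gesture ID stored where a frame carries no prediction (invalid frame).
NO_PREDICTION = -1


@dataclass(frozen=True)
class TimelineSpec:
    """Timing layout shared by every trial in a cohort.

    Parameters
    ----------
    frame_period : int
        Milliseconds between consecutive video frames (40 ms = 25 Hz).
    trial_duration : int
        Trial length in ms; must be an exact multiple of ``frame_period``.
    phase_boundaries : (int, int)
        Start of the early-grasping and firm-grasping phases, in ms.
        Defaults are the cohort-averaged hand/object contact (1020 ms)
        and firm-hold (1604 ms) times.
    """

    frame_period: int = 40
    trial_duration: int = 4480
    phase_boundaries: tuple[int, int] = (1020, 1604)

    def __post_init__(self) -> None:
        if self.frame_period <= 0:
            raise ValueError(f"frame_period must be positive, got {self.frame_period}")
        if self.trial_duration % self.frame_period != 0:
            raise ValueError(
                f"trial_duration {self.trial_duration} is not a multiple of "
                f"frame_period {self.frame_period}"
            )
        b1, b2 = self.phase_boundaries
        if not (0 < b1 < b2 < self.trial_duration):
            raise ValueError(
                f"phase boundaries must satisfy 0 < {b1} < {b2} < {self.trial_duration}"
            )

    @property
    def n_frames(self) -> int:
        return self.trial_duration // self.frame_period

    @property
    def frame_times(self) -> np.ndarray:
        """Start time of every frame, in ms (shape ``(n_frames,)``)."""
        return np.arange(self.n_frames) * self.frame_period


def frames_in_window(spec: TimelineSpec, start: int, end: int) -> range:
    """Indices of frames whose start time t satisfies ``start <= t < end``.

    Both bounds must be multiples of ``spec.frame_period`` and lie inside
    ``[0, trial_duration]``.  Returns a ``range`` (set-like: supports
    ``len``, ``in`` and ``set()``).
    """
    if start < 0 or start >= spec.trial_duration:
        raise ValueError(f"window start {start} ms outside trial [0, {spec.trial_duration})")
    if end <= start or end > spec.trial_duration:
        raise ValueError(
            f"window end {end} ms outside ({start}, {spec.trial_duration}]"
        )
    if start % spec.frame_period or end % spec.frame_period:
        raise ValueError(
            f"window bounds ({start}, {end}) must be multiples of the "
            f"{spec.frame_period} ms frame period"
        )
    return range(start // spec.frame_period, end // spec.frame_period)


def phase_of(spec: TimelineSpec, time: float) -> str:
    """Grasp phase containing ``time`` (ms): reaching, early or firm grasping.

    Phases are half-open, so the boundary instant belongs to the later phase.
    """
    if time < 0 or time >= spec.trial_duration:
        raise ValueError(f"time {time} ms outside trial [0, {spec.trial_duration})")
    b1, b2 = spec.phase_boundaries
    if time < b1:
        return PHASES[0]
    if time < b2:
        return PHASES[1]
    return PHASES[2]


def cohort_size(
    n_subjects: int, n_gestures: int, n_objects_per_gesture: int, n_repetitions: int
) -> int:
    """Trial count of a fully crossed cohort design."""
    counts = (n_subjects, n_gestures, n_objects_per_gesture, n_repetitions)
    if any(c <= 0 for c in counts):
        raise ValueError(f"all cohort dimensions must be positive, got {counts}")
    return int(np.prod(counts))


@dataclass(frozen=True)
class GraspTaxonomy:
    """The grasp-gesture/object vocabulary: 10 gestures acting on 18 objects.

    Each gesture is exercised on a small set of objects (three for most
    gestures); the ``pairs`` list enumerates every (gesture, object)
    combination a cohort contains.  Loaded from a packaged plain-text
    table so generators and scorers share one vocabulary.
    """

    gesture_names: dict[int, str]
    pairs: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if sorted(self.gesture_names) != sorted({g for g, _ in self.pairs}):
            raise ValueError("gesture_names and pairs disagree on gesture IDs")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate (gesture, object) pair in taxonomy")

    @classmethod
    def default(cls) -> "GraspTaxonomy":
        """The packaged 10-gesture / 18-object taxonomy."""
        text = (resources.files("sweetfuse.data") / "grasp_taxonomy.tsv").read_text()
        names: dict[int, str] = {}
        pairs: list[tuple[int, str]] = []
        for line in text.strip().splitlines()[1:]:
            gid_s, gname, oname = line.split("\t")
            gid = int(gid_s)
            names[gid] = gname
            pairs.append((gid, oname))
        return cls(gesture_names=names, pairs=tuple(pairs))

    @property
    def gestures(self) -> tuple[int, ...]:
        return tuple(sorted(self.gesture_names))

    @property
    def objects(self) -> tuple[str, ...]:
        return tuple(sorted({o for _, o in self.pairs}))

    def objects_for(self, gesture: int) -> tuple[str, ...]:
        return tuple(o for g, o in self.pairs if g == gesture)

    def has_pair(self, gesture: int, obj: str) -> bool:
        return (gesture, obj) in self.pairs


@dataclass(frozen=True, order=True)
class TrialKey:
    """Identity of one grasp trial within a cohort."""

    subject: int
    gesture: int
    object: str
    repetition: int

    def validate(self, taxonomy: GraspTaxonomy, n_subjects: int = 30,
                 n_repetitions: int = 4) -> None:
        if not 1 <= self.subject <= n_subjects:
            raise ValueError(f"subject {self.subject} outside 1..{n_subjects}")
        if not 1 <= self.repetition <= n_repetitions:
            raise ValueError(f"repetition {self.repetition} outside 1..{n_repetitions}")
        if not taxonomy.has_pair(self.gesture, self.object):
            raise ValueError(
                f"(gesture={self.gesture}, object={self.object!r}) is not in the taxonomy"
            )


class FrameRecord(NamedTuple):
    """One video frame's classifier output.

    ``valid`` means the target object was detectable in the frame;
    predictions are present exactly when the frame is valid.
    """

    frame_index: int
    time: int
    valid: bool
    predicted_gesture: int | None
    predicted_object: str | None


class EmgRecord(NamedTuple):
    """One sEMG decision point: the muscle classifier always votes."""

    time: int
    predicted_gesture: int


@dataclass
class TrialStream:
    """Time-indexed classifier outputs for one grasp trial.

    Frames are stored as parallel arrays for speed; ``frames()`` and
    ``emg_records()`` yield record views.  Invalid frames carry
    ``NO_PREDICTION`` / ``None`` in the prediction arrays.
    """

    key: TrialKey
    true_gesture: int
    frame_time: np.ndarray          # int ms, shape (n_frames,)
    frame_valid: np.ndarray         # bool,   shape (n_frames,)
    predicted_gesture: np.ndarray   # int,    NO_PREDICTION where invalid
    predicted_object: np.ndarray    # object (str or None)
    emg_time: np.ndarray            # int ms, shape (n_emg,)
    emg_predicted_gesture: np.ndarray  # int, shape (n_emg,)

    def __post_init__(self) -> None:
        self.frame_time = np.asarray(self.frame_time, dtype=np.int64)
        self.frame_valid = np.asarray(self.frame_valid, dtype=bool)
        self.predicted_gesture = np.asarray(self.predicted_gesture, dtype=np.int64)
        self.predicted_object = np.asarray(self.predicted_object, dtype=object)
        self.emg_time = np.asarray(self.emg_time, dtype=np.int64)
        self.emg_predicted_gesture = np.asarray(self.emg_predicted_gesture, dtype=np.int64)

    def validate(self, spec: TimelineSpec) -> None:
        """Check the structural invariants; raise ValueError naming the defect."""
        n = spec.n_frames
        if len(self.frame_time) != n:
            raise ValueError(
                f"trial {self.key}: expected {n} frames, got {len(self.frame_time)}"
            )
        if not np.array_equal(self.frame_time, spec.frame_times):
            raise ValueError(f"trial {self.key}: frame times disagree with the timeline")
        if self.true_gesture != self.key.gesture:
            raise ValueError(
                f"trial {self.key}: true_gesture {self.true_gesture} != key gesture"
            )
        has_g = self.predicted_gesture != NO_PREDICTION
        has_o = np.array([o is not None for o in self.predicted_object])
        if not (np.array_equal(has_g, self.frame_valid)
                and np.array_equal(has_o, self.frame_valid)):
            raise ValueError(
                f"trial {self.key}: predictions must be present iff the frame is valid"
            )
        if len(self.emg_time) != len(self.emg_predicted_gesture):
            raise ValueError(f"trial {self.key}: ragged sEMG arrays")
        if len(self.emg_time) and (
            self.emg_time.min() < 0 or self.emg_time.max() >= spec.trial_duration
        ):
            raise ValueError(f"trial {self.key}: sEMG time outside the trial")
        if np.any(np.diff(self.emg_time) <= 0):
            raise ValueError(f"trial {self.key}: sEMG times not strictly increasing")

    def frames(self) -> Iterator[FrameRecord]:
        for i in range(len(self.frame_time)):
            valid = bool(self.frame_valid[i])
            yield FrameRecord(
                frame_index=i,
                time=int(self.frame_time[i]),
                valid=valid,
                predicted_gesture=int(self.predicted_gesture[i]) if valid else None,
                predicted_object=self.predicted_object[i] if valid else None,
            )

    def emg_records(self) -> Iterator[EmgRecord]:
        for t, g in zip(self.emg_time, self.emg_predicted_gesture):
            yield EmgRecord(time=int(t), predicted_gesture=int(g))

    @classmethod
    def from_records(
        cls,
        key: TrialKey,
        true_gesture: int,
        frames: Sequence[FrameRecord],
        emg: Sequence[EmgRecord],
    ) -> "TrialStream":
        return cls(
            key=key,
            true_gesture=true_gesture,
            frame_time=np.array([f.time for f in frames], dtype=np.int64),
            frame_valid=np.array([f.valid for f in frames], dtype=bool),
            predicted_gesture=np.array(
                [f.predicted_gesture if f.valid else NO_PREDICTION for f in frames],
                dtype=np.int64,
            ),
            predicted_object=np.array(
                [f.predicted_object if f.valid else None for f in frames], dtype=object
            ),
            emg_time=np.array([e.time for e in emg], dtype=np.int64),
            emg_predicted_gesture=np.array(
                [e.predicted_gesture for e in emg], dtype=np.int64
            ),
        )
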