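"""Plurality-vote decisions per modality and max-confidence integration.

Each modality condenses its sweet-period decision stream into a single
(label, confidence) pair by plurality vote; the confidence is the
winning share of the votes actually cast.  Integration keeps whichever
modality is more confident.  Vision may abstain (no valid frame in its
window); sEMG always votes, so it is the fallback — and it also wins
exact confidence ties, treating the always-available modality as the
default.  Ties inside a vote go to the lowest gesture ID so evaluation
is deterministic.

The arithmetic behind the integration: with at most ``v`` valid frames
in the vision window and at least one misclassified, vision confidence
is capped at (v-1)/v — e.g. 75% for v=4 — which is below the typical
sEMG confidence, so sparse or noisy vision windows automatically defer
to the muscle signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import TrialKey, TrialStream
from .temporal import SweetPeriod

__all__ = [
    "VoteDecision",
    "FusionOutcome",
    "plurality_vote",
    "vision_decision",
    "emg_decision",
    "fuse",
    "fuse_trial",
    "max_vision_confidence_bound",
]


@dataclass(frozen=True)
class VoteDecision:
    """Result of a plurality vote: winning label and its vote share."""

    label: int | None
    confidence: float
    votes_cast: int
    present: bool

    def __post_init__(self) -> None:
        if self.present:
            if self.label is None or self.votes_cast < 1:
                raise ValueError("present decision needs a label and votes")
            if not 0.0 < self.confidence <= 1.0:
                raise ValueError(f"confidence {self.confidence} outside (0, 1]")
        else:
            if self.confidence != 0.0 or self.votes_cast != 0 or self.label is not None:
                raise ValueError("absent decision must carry no label, votes or confidence")

    @classmethod
    def absent(cls) -> "VoteDecision":
        return cls(label=None, confidence=0.0, votes_cast=0, present=False)


@dataclass(frozen=True)
class FusionOutcome:
    """Integrated classification of one trial."""

    key: TrialKey
    vision: VoteDecision
    emg: VoteDecision
    chosen_source: str   # "vision" | "emg"
    final_label: int
    correct: bool


def plurality_vote(votes: Sequence[int]) -> VoteDecision:
    """Most frequent label and its share of the votes cast.

    Empty input yields an absent decision; a tie among top labels is
    broken toward the lowest gesture ID.
    """
    votes = np.asarray(votes, dtype=np.int64)
    if votes.size == 0:
        return VoteDecision.absent()
    labels, counts = np.unique(votes, return_counts=True)  # labels ascending
    winner = int(labels[np.argmax(counts)])                # first max = lowest ID
    top = int(counts.max())
    return VoteDecision(
        label=winner,
        confidence=top / votes.size,
        votes_cast=int(votes.size),
        present=True,
    )


def vision_decision(trial: TrialStream, window: SweetPeriod | tuple[int, int]) -> VoteDecision:
    """Plurality vote over gesture predictions of valid frames in the window."""
    start, end = (window.start, window.end) if isinstance(window, SweetPeriod) else window
    use = (trial.frame_time >= start) & (trial.frame_time < end) & trial.frame_valid
    return plurality_vote(trial.predicted_gesture[use])


def emg_decision(trial: TrialStream, window: tuple[int, int]) -> VoteDecision:
    """Plurality vote over every sEMG decision point in the window.

    sEMG has no validity concept — every point votes — so an empty
    window marks a malformed trial and raises.
    """
    start, end = window
    use = (trial.emg_time >= start) & (trial.emg_time < end)
    if not use.any():
        raise ValueError(
            f"trial {trial.key}: no sEMG decision points in [{start}, {end}) ms"
        )
    return plurality_vote(trial.emg_predicted_gesture[use])


def fuse(vision: VoteDecision, emg: VoteDecision) -> tuple[str, int]:
    """Pick the more confident modality; returns (chosen_source, label).

    Vision wins only with a strictly higher confidence; ties and absent
    vision fall back to sEMG.  sEMG must be present.
    """
    if not emg.present:
        raise ValueError("sEMG decision is absent; the fallback modality must vote")
    if vision.present and vision.confidence > emg.confidence:
        return "vision", int(vision.label)
    return "emg", int(emg.label)


def fuse_trial(
    trial: TrialStream,
    vision_window: SweetPeriod | tuple[int, int],
    emg_window: tuple[int, int],
) -> FusionOutcome:
    """End-to-end integration of one trial's two decision streams."""
    vis = vision_decision(trial, vision_window)
    emg = emg_decision(trial, emg_window)
    source, label = fuse(vis, emg)
    return FusionOutcome(
        key=trial.key,
        vision=vis,
        emg=emg,
        chosen_source=source,
        final_label=label,
        correct=label == trial.true_gesture,
    )


def max_vision_confidence_bound(
    window_frames: int, max_valid: int, min_errors: int
) -> float:
    """Highest plurality confidence attainable under sparse, noisy vision.

    Over all vote configurations with at most ``max_valid`` votes cast
    (out of ``window_frames`` possible) and at least ``min_errors`` votes
    not for the winner, the best case is every vote cast and all errors
    scattered: confidence (max_valid - min_errors) / max_valid.
    """
    if not 0 < max_valid <= window_frames:
        raise ValueError(f"max_valid must lie in 1..{window_frames}, got {max_valid}")
    if not 0 <= min_errors <= max_valid:
        raise ValueError(
            f"min_errors must lie in 0..{max_valid}, got {min_errors}"
        )
    return (max_valid - min_errors) / max_valid
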