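"""Synthetic cohorts of grasp-trial decision streams.

The generator emulates the statistical structure of an egocentric-video +
sEMG grasp study: 30 subjects each perform 10 grasp gestures on their
taxonomy objects, 4 repetitions each (3,600 trials); a 4,480 ms trial
yields 112 video frames at 25 Hz.  What is simulated is the *output* of
upstream classifiers — per-frame validity and predicted labels — never
images or waveforms.

Frame validity follows a piecewise-linear probability curve: the target
object is most visible shortly after movement onset (peak at 160 ms,
while the subject still fixates the object), then the reaching hand
progressively occludes it, and during firm grasping detectability stays
below ~10%.  A per-trial uniform time jitter shifts the curve, modelling
subjects touching the object at different moments.  Default curve
parameters are calibrated so the mean validity over the first 320 ms of
the trial is ≈53% and the best ≥5-frame anchored window is [0, 320) ms.

The sEMG stream uses a two-level error model: a per-trial dominant label
(correct with probability ``emg_trial_accuracy``), voted at each decision
point with probability ``emg_consistency``.  This reproduces the two
features real myoelectric streams show jointly — moderate trial-level
accuracy (~85.5%) and high, stable plurality confidence (>75% in most
trials) — which no per-point i.i.d. error model can achieve at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    NO_PREDICTION,
    GraspTaxonomy,
    TimelineSpec,
    TrialKey,
    TrialStream,
)
from .stream_io import ExperimentConfig

__all__ = [
    "GeneratorParams",
    "validity_probability",
    "expected_validity",
    "generate_trial",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort generator.

    Times in ms, probabilities in [0, 1].  ``gesture_confusion``, if
    given, maps each true gesture ID to a mapping {wrong label:
    probability} used for vision misclassifications; by default errors
    are uniform over the 9 non-true gestures.
    """

    taxonomy: GraspTaxonomy
    spec: TimelineSpec = TimelineSpec()
    subjects: int = 30
    repetitions: int = 4
    # validity curve
    validity_baseline: float = 0.47
    validity_peak: float = 0.58
    validity_peak_time: int = 160
    validity_decline_end: int = 1604
    validity_floor: float = 0.08
    time_jitter: float = 120.0          # curve shift ~ U(-j, +j) per trial
    validity_persistence: float = 0.0   # first-order carry-over of validity
    # vision classifier operating point (among valid frames)
    vision_gesture_accuracy: float = 0.92
    vision_object_accuracy: float = 0.97
    gesture_confusion: Mapping[int, Mapping[int, float]] | None = None
    # sEMG stream
    emg_period: int = 40
    emg_trial_accuracy: float = 0.855
    emg_consistency: float = 0.90

    def __post_init__(self) -> None:
        probs = (
            self.validity_baseline, self.validity_peak, self.validity_floor,
            self.vision_gesture_accuracy, self.vision_object_accuracy,
            self.emg_trial_accuracy, self.emg_consistency,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"probabilities must lie in [0, 1]: {probs}")
        if not (self.validity_peak >= self.validity_baseline >= self.validity_floor):
            raise ValueError("need peak >= baseline >= floor validity")
        if self.subjects <= 0 or self.repetitions <= 0:
            raise ValueError("cohort dimensions must be positive")
        if not 0 < self.validity_peak_time < self.validity_decline_end:
            raise ValueError("need 0 < peak time < decline end")
        if self.emg_period <= 0:
            raise ValueError("emg_period must be positive")
        if not 0.0 <= self.validity_persistence < 1.0:
            raise ValueError("validity_persistence must lie in [0, 1)")

    @classmethod
    def from_config(
        cls, config: ExperimentConfig, taxonomy: GraspTaxonomy | None = None
    ) -> "GeneratorParams":
        return cls(
            taxonomy=taxonomy or GraspTaxonomy.default(),
            spec=config.timeline(),
            subjects=config.subjects,
            repetitions=config.repetitions,
            validity_baseline=config.validity_baseline,
            validity_peak=config.validity_peak,
            validity_peak_time=config.validity_peak_time,
            validity_decline_end=config.validity_decline_end,
            validity_floor=config.validity_floor,
            time_jitter=config.time_jitter,
            vision_gesture_accuracy=config.vision_gesture_accuracy,
            vision_object_accuracy=config.vision_object_accuracy,
            emg_period=config.emg_period,
            emg_trial_accuracy=config.emg_trial_accuracy,
            emg_consistency=config.emg_consistency,
        )


def validity_probability(params: GeneratorParams, time) -> np.ndarray | float:
    """Frame-validity probability at ``time`` ms (vectorised, continuous).

    Piecewise linear: baseline at t<=0, rise to the peak over
    [0, peak_time], linear decline to the floor over
    [peak_time, decline_end], constant floor afterwards.
    """
    t = np.asarray(time, dtype=float)
    b, p, f = params.validity_baseline, params.validity_peak, params.validity_floor
    tp, te = float(params.validity_peak_time), float(params.validity_decline_end)
    rise = b + (p - b) * np.clip(t, 0.0, tp) / tp
    decline = p - (p - f) * np.clip(t - tp, 0.0, te - tp) / (te - tp)
    out = np.where(t <= tp, rise, decline)
    if np.isscalar(time):
        return float(out)
    return out


def expected_validity(params: GeneratorParams, time, n_grid: int = 801):
    """Marginal validity probability at ``time`` after averaging the
    per-trial jitter (numerical quadrature over the uniform shift)."""
    if params.time_jitter == 0:
        return validity_probability(params, time)
    shifts = np.linspace(-params.time_jitter, params.time_jitter, n_grid)
    t = np.atleast_1d(np.asarray(time, dtype=float))
    vals = validity_probability(params, t[:, None] - shifts[None, :]).mean(axis=1)
    if np.isscalar(time):
        return float(vals[0])
    return vals


def _trial_rng(seed: int, params: GeneratorParams, key: TrialKey) -> np.random.Generator:
    """Per-trial RNG stream derived from the master seed and the trial key.

    The derivation (seed, subject, gesture, taxonomy pair index,
    repetition) is stable, so any single trial can be regenerated in
    isolation and cohort generation order is irrelevant.
    """
    pair_index = params.taxonomy.pairs.index((key.gesture, key.object))
    ss = np.random.SeedSequence([int(seed), key.subject, key.gesture,
                                 pair_index, key.repetition])
    return np.random.default_rng(ss)


def _wrong_labels(labels: Sequence, true_label) -> np.ndarray:
    return np.array([l for l in labels if l != true_label], dtype=object)


def generate_trial(
    params: GeneratorParams, key: TrialKey, rng: np.random.Generator
) -> TrialStream:
    """Draw one trial's vision and sEMG decision streams.

    Draw order is fixed (jitter, validity, gesture predictions, object
    predictions, sEMG dominant label, sEMG votes) so a given RNG stream
    always yields the same trial.
    """
    spec = params.spec
    times = spec.frame_times
    n = spec.n_frames
    gestures = params.taxonomy.gestures
    true_g = key.gesture

    jitter = rng.uniform(-params.time_jitter, params.time_jitter) if params.time_jitter else 0.0
    p_valid = validity_probability(params, times - jitter)

    u = rng.random(n)
    if params.validity_persistence > 0.0:
        # first-order carry-over: a frame repeats its predecessor's state
        # with probability `validity_persistence`, else draws fresh
        repeat = rng.random(n) < params.validity_persistence
        valid = np.zeros(n, dtype=bool)
        valid[0] = u[0] < p_valid[0]
        for i in range(1, n):
            valid[i] = valid[i - 1] if repeat[i] else u[i] < p_valid[i]
    else:
        valid = u < p_valid

    # vision gesture predictions among valid frames
    pred_g = np.full(n, NO_PREDICTION, dtype=np.int64)
    correct_g = rng.random(n) < params.vision_gesture_accuracy
    if params.gesture_confusion is not None:
        row = params.gesture_confusion[true_g]
        wrong_ids = np.array(sorted(row), dtype=np.int64)
        weights = np.array([row[i] for i in wrong_ids], dtype=float)
        weights = weights / weights.sum()
        errors_g = rng.choice(wrong_ids, size=n, p=weights)
    else:
        wrong_ids = np.array([g for g in gestures if g != true_g], dtype=np.int64)
        errors_g = wrong_ids[rng.integers(0, len(wrong_ids), size=n)]
    pred_g[valid] = np.where(correct_g[valid], true_g, errors_g[valid])

    # vision object predictions among valid frames
    pred_o = np.full(n, None, dtype=object)
    correct_o = rng.random(n) < params.vision_object_accuracy
    wrong_objs = _wrong_labels(params.taxonomy.objects, key.object)
    errors_o = wrong_objs[rng.integers(0, len(wrong_objs), size=n)]
    pred_o[valid] = np.where(correct_o[valid], key.object, errors_o[valid])

    # sEMG: dominant trial label, voted with per-point consistency
    wrong_g = np.array([g for g in gestures if g != true_g], dtype=np.int64)
    if rng.random() < params.emg_trial_accuracy:
        dominant = true_g
    else:
        dominant = int(rng.choice(wrong_g))
    emg_times = np.arange(0, spec.trial_duration, params.emg_period, dtype=np.int64)
    m = len(emg_times)
    votes_dominant = rng.random(m) < params.emg_consistency
    other = np.array([g for g in gestures if g != dominant], dtype=np.int64)
    emg_errors = other[rng.integers(0, len(other), size=m)]
    emg_pred = np.where(votes_dominant, dominant, emg_errors)

    return TrialStream(
        key=key,
        true_gesture=true_g,
        frame_time=times,
        frame_valid=valid,
        predicted_gesture=pred_g,
        predicted_object=pred_o,
        emg_time=emg_times,
        emg_predicted_gesture=emg_pred,
    )


def generate_cohort(params: GeneratorParams, seed: int) -> list[TrialStream]:
    """One trial per (subject, taxonomy pair, repetition), reproducibly.

    Each trial gets its own RNG stream derived from ``seed`` and the
    trial key, so two cohorts with the same seed are identical and a
    subset of subjects reproduces the corresponding trials exactly.
    """
    cohort: list[TrialStream] = []
    for subject in range(1, params.subjects + 1):
        for gesture, obj in params.taxonomy.pairs:
            for rep in range(1, params.repetitions + 1):
                key = TrialKey(subject=subject, gesture=gesture,
                               object=obj, repetition=rep)
                rng = _trial_rng(seed, params, key)
                cohort.append(generate_trial(params, key, rng))
    cohort.sort(key=lambda t: t.key)
    return cohort
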