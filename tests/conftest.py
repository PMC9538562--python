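import numpy as np
import pytest

from sweetfuse import (
    NO_PREDICTION,
    GeneratorParams,
    GraspTaxonomy,
    TimelineSpec,
    TrialKey,
    TrialStream,
    generate_cohort,
)


@pytest.fixture(scope="session")
def taxonomy():
    return GraspTaxonomy.default()


@pytest.fixture(scope="session")
def spec():
    return TimelineSpec()


@pytest.fixture(scope="session")
def small_cohort(taxonomy):
    """Two-subject default-parameter cohort (240 trials)."""
    params = GeneratorParams(taxonomy=taxonomy, subjects=2)
    return generate_cohort(params, seed=11)


def make_trial(
    spec: TimelineSpec,
    key: TrialKey,
    valid_frames: dict[int, int] | None = None,
    object_preds: dict[int, str] | None = None,
    emg_votes: list[int] | None = None,
    emg_period: int = 40,
) -> TrialStream:
    """Hand-build a trial: ``valid_frames`` maps frame index -> predicted
    gesture; every other frame is invalid.  ``emg_votes`` fills the whole
    trial cyclically (default: always the true gesture)."""
    n = spec.n_frames
    valid = np.zeros(n, dtype=bool)
    pred_g = np.full(n, NO_PREDICTION, dtype=np.int64)
    pred_o = np.full(n, None, dtype=object)
    for idx, g in (valid_frames or {}).items():
        valid[idx] = True
        pred_g[idx] = g
        pred_o[idx] = (object_preds or {}).get(idx, key.object)
    emg_time = np.arange(0, spec.trial_duration, emg_period, dtype=np.int64)
    votes = emg_votes or [key.gesture]
    emg_pred = np.array(
        [votes[i % len(votes)] for i in range(len(emg_time))], dtype=np.int64
    )
    return TrialStream(
        key=key,
        true_gesture=key.gesture,
        frame_time=spec.frame_times,
        frame_valid=valid,
        predicted_gesture=pred_g,
        predicted_object=pred_o,
        emg_time=emg_time,
        emg_predicted_gesture=emg_pred,
    )


@pytest.fixture
def trial_factory(spec):
    def factory(key=None, **kwargs):
        key = key or TrialKey(subject=1, gesture=1, object="Bottle", repetition=1)
        return make_trial(spec, key, **kwargs)

    return factory
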