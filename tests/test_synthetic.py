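import numpy as np
import pytest
from scipy import stats

from sweetfuse import (
    GeneratorParams,
    TrialKey,
    expected_validity,
    generate_cohort,
    generate_trial,
    validity_probability,
    vision_decision,
)
from sweetfuse.synthetic import _trial_rng


@pytest.fixture(scope="module")
def params(taxonomy):
    return GeneratorParams(taxonomy=taxonomy)


def noiseless(taxonomy, **overrides):
    base = dict(
        taxonomy=taxonomy,
        validity_baseline=1.0,
        validity_peak=1.0,
        validity_floor=1.0,
        time_jitter=0.0,
        vision_gesture_accuracy=1.0,
        vision_object_accuracy=1.0,
        emg_trial_accuracy=1.0,
        emg_consistency=1.0,
    )
    base.update(overrides)
    return GeneratorParams(**base)


class TestValidityCurve:
    def test_landmarks(self, params):
        assert validity_probability(params, 160) == pytest.approx(params.validity_peak)
        assert validity_probability(params, 0) == pytest.approx(params.validity_baseline)
        assert validity_probability(params, 4440) == pytest.approx(params.validity_floor)
        assert validity_probability(params, -500) == pytest.approx(params.validity_baseline)

    def test_piecewise_linear_and_continuous(self, params):
        t = np.linspace(0, 4479, 3000)
        v = validity_probability(params, t)
        # steepest segment is the rise; adjacent samples differ by at
        # most slope * step
        max_slope = (params.validity_peak - params.validity_baseline) / 160
        step = t[1] - t[0]
        assert np.all(np.abs(np.diff(v)) <= max_slope * step + 1e-12)
        assert v.min() >= params.validity_floor - 1e-12
        assert v.max() <= params.validity_peak + 1e-12

    def test_jitter_marginal_equals_pure_curve_when_jitter_off(self, taxonomy):
        p = GeneratorParams(taxonomy=taxonomy, time_jitter=0.0)
        t = np.arange(0, 4480, 40)
        assert np.allclose(expected_validity(p, t), validity_probability(p, t))

    def test_sweet_window_mean_validity_near_half(self, params):
        """Monte-Carlo over >=10^4 frames: early-window validity ~53%."""
        cohort = generate_cohort(
            GeneratorParams(taxonomy=params.taxonomy, subjects=2), seed=5
        )
        valid = np.vstack([t.frame_valid[:8] for t in cohort])
        assert valid.size >= 1900
        p_hat = valid.mean()
        p_exp = expected_validity(params, np.arange(8) * 40.0).mean()
        se = np.sqrt(p_exp * (1 - p_exp) / valid.size)
        assert abs(p_hat - p_exp) < 4 * se
        assert 0.45 < p_hat < 0.60


class TestGenerateTrial:
    def test_noiseless_trial_is_perfect(self, taxonomy):
        p = noiseless(taxonomy)
        key = TrialKey(subject=1, gesture=3, object="Book", repetition=1)
        trial = generate_trial(p, key, _trial_rng(0, p, key))
        assert trial.frame_valid.all()
        assert (trial.predicted_gesture == 3).all()
        assert all(o == "Book" for o in trial.predicted_object)
        assert (trial.emg_predicted_gesture == 3).all()

    def test_zero_validity_means_vision_always_abstains(self, taxonomy):
        p = noiseless(taxonomy, validity_baseline=0.0, validity_peak=0.0,
                      validity_floor=0.0)
        key = TrialKey(subject=1, gesture=1, object="Can", repetition=2)
        trial = generate_trial(p, key, _trial_rng(0, p, key))
        assert not trial.frame_valid.any()
        assert not vision_decision(trial, (0, 4480)).present

    def test_same_seed_reproduces_trial(self, params):
        key = TrialKey(subject=7, gesture=5, object="Jar", repetition=3)
        t1 = generate_trial(params, key, _trial_rng(42, params, key))
        t2 = generate_trial(params, key, _trial_rng(42, params, key))
        assert np.array_equal(t1.frame_valid, t2.frame_valid)
        assert np.array_equal(t1.predicted_gesture, t2.predicted_gesture)
        assert np.array_equal(t1.emg_predicted_gesture, t2.emg_predicted_gesture)

    def test_validity_persistence_runs(self, taxonomy):
        p = GeneratorParams(taxonomy=taxonomy, validity_persistence=0.8)
        key = TrialKey(subject=1, gesture=1, object="Mug", repetition=1)
        trial = generate_trial(p, key, _trial_rng(3, p, key))
        trial.validate(p.spec)


class TestGenerateCohort:
    def test_default_design_sizes(self, taxonomy):
        one_subject = GeneratorParams(taxonomy=taxonomy, subjects=1)
        cohort = generate_cohort(one_subject, seed=0)
        assert len(cohort) == 120  # 30 gesture-object pairs x 4 repetitions
        keys = {t.key for t in cohort}
        assert len(keys) == 120

    def test_full_cohort_is_3600_trials(self, taxonomy):
        # count keys without generating: 30 subjects x 30 pairs x 4 reps
        params = GeneratorParams(taxonomy=taxonomy)
        assert params.subjects * len(taxonomy.pairs) * params.repetitions == 3600

    def test_seeding_contract(self, taxonomy):
        p = GeneratorParams(taxonomy=taxonomy, subjects=1)
        a = generate_cohort(p, seed=1)
        b = generate_cohort(p, seed=1)
        c = generate_cohort(p, seed=2)
        assert all(
            np.array_equal(x.frame_valid, y.frame_valid) for x, y in zip(a, b)
        )
        assert any(
            not np.array_equal(x.frame_valid, y.frame_valid) for x, y in zip(a, c)
        )

    def test_trial_regenerable_in_isolation(self, taxonomy):
        p = GeneratorParams(taxonomy=taxonomy, subjects=2)
        cohort = generate_cohort(p, seed=9)
        probe = cohort[57]
        rebuilt = generate_trial(p, probe.key, _trial_rng(9, p, probe.key))
        assert np.array_equal(probe.frame_valid, rebuilt.frame_valid)
        assert np.array_equal(probe.predicted_gesture, rebuilt.predicted_gesture)
        assert np.array_equal(
            probe.emg_predicted_gesture, rebuilt.emg_predicted_gesture
        )


@pytest.fixture(scope="module")
def cohort(taxonomy):
    return generate_cohort(GeneratorParams(taxonomy=taxonomy, subjects=5), seed=2)


class TestStatisticalStructure:
    def test_vision_accuracy_recovered(self, cohort, params):
        valid = np.vstack([t.frame_valid for t in cohort])
        pred = np.vstack([t.predicted_gesture for t in cohort])
        truth = np.array([t.true_gesture for t in cohort])[:, None]
        n_valid = valid.sum()
        acc = (pred == truth)[valid].mean()
        se = np.sqrt(0.92 * 0.08 / n_valid)
        assert abs(acc - params.vision_gesture_accuracy) < 4 * se

    def test_vision_errors_uniform_over_other_gestures(self, cohort):
        wrong = []
        for t in cohort:
            mask = t.frame_valid & (t.predicted_gesture != t.true_gesture)
            wrong.extend((t.true_gesture, g) for g in t.predicted_gesture[mask])
        # pool errors of one gesture: should be uniform over the 9 others
        errors_g1 = [g for true, g in wrong if true == 1]
        assert len(errors_g1) > 100
        counts = np.bincount(errors_g1, minlength=11)[2:11]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-4

    def test_confusion_table_error_model(self, taxonomy):
        confusion = {g: {1 if g != 1 else 2: 1.0} for g in taxonomy.gestures}
        p = GeneratorParams(
            taxonomy=taxonomy, subjects=1, gesture_confusion=confusion,
            vision_gesture_accuracy=0.5,
        )
        cohort = generate_cohort(p, seed=4)
        for t in cohort:
            mask = t.frame_valid & (t.predicted_gesture != t.true_gesture)
            target = 1 if t.true_gesture != 1 else 2
            assert (t.predicted_gesture[mask] == target).all()

    def test_emg_confidence_typically_above_three_quarters(self, cohort):
        from sweetfuse import emg_decision

        confs = [emg_decision(t, (1100, 1400)).confidence for t in cohort]
        share = np.mean([c > 0.75 for c in confs])
        assert share > 0.6  # "stable and higher than 75% in most circumstances"

    def test_emg_trial_accuracy_near_operating_point(self, cohort, params):
        from sweetfuse import emg_decision

        correct = [
            emg_decision(t, (1100, 1400)).label == t.true_gesture for t in cohort
        ]
        acc = np.mean(correct)
        se = np.sqrt(0.855 * 0.145 / len(correct))
        assert abs(acc - params.emg_trial_accuracy) < 4 * se


class TestParamValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"validity_baseline": 1.2},
            {"validity_peak": 0.3, "validity_baseline": 0.5},
            {"validity_floor": 0.6, "validity_baseline": 0.5, "validity_peak": 0.7},
            {"subjects": 0},
            {"emg_period": 0},
            {"validity_persistence": 1.0},
        ],
    )
    def test_bad_params_rejected(self, taxonomy, overrides):
        with pytest.raises(ValueError):
            GeneratorParams(taxonomy=taxonomy, **overrides)
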