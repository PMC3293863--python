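import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortcluster.cohort import CohortError
from cohortcluster.preprocess import (
    DegenerateMarkerError,
    PipelineVariant,
    age_adjust,
    complete_cases,
    impute_median,
    normal_transform,
    preprocess,
    sample_skewness,
    zscore_normalize,
)

from .conftest import make_cohort


def _skew_oracle(values):
    """Independent evaluation of the adjusted Fisher-Pearson skewness."""
    x = np.asarray(values, float)
    n = len(x)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    g1 = m3 / m2**1.5
    return g1 * np.sqrt(n * (n - 1)) / (n - 2)


class TestSampleSkewness:
    def test_symmetric_data_is_zero(self):
        assert sample_skewness(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.0)

    def test_matches_direct_moment_formula(self):
        x = [1.0, 1.0, 1.0, 10.0]
        assert sample_skewness(np.array(x)) == pytest.approx(_skew_oracle(x), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateMarkerError):
            sample_skewness(np.array([5.0, 5.0, 5.0]))

    def test_too_short_errors(self):
        with pytest.raises(DegenerateMarkerError):
            sample_skewness(np.array([1.0, 2.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=40))
    def test_agrees_with_oracle_on_random_inputs(self, xs):
        x = np.asarray(xs)
        if np.std(x, ddof=1) < 1e-9:
            return
        assert sample_skewness(x) == pytest.approx(_skew_oracle(x), rel=1e-9, abs=1e-9)


class TestNormalTransform:
    def test_all_normal_markers_untouched(self, rng):
        X = rng.normal(10, 2, (500, 4))
        cohort = make_cohort(X)
        out, transformed = normal_transform(cohort)
        assert transformed == set()
        np.testing.assert_array_equal(out.markers, X)

    def test_lognormal_marker_selected_and_fixed(self, rng):
        X = np.column_stack([rng.normal(0, 1, 2000), np.exp(rng.normal(0, 1, 2000))])
        cohort = make_cohort(X)
        out, transformed = normal_transform(cohort)
        assert transformed == {"m01"}
        assert abs(sample_skewness(out.markers[:, 1])) <= 1.0
        np.testing.assert_array_equal(out.markers[:, 0], X[:, 0])

    def test_gate_agrees_with_bruteforce_recomputation(self, rng):
        X = np.column_stack([
            rng.normal(size=800),
            np.exp(rng.normal(size=800)),
            rng.uniform(1, 2, 800),
            np.exp(rng.normal(0, 1.5, 800)),
        ])
        cohort = make_cohort(X)
        _, transformed = normal_transform(cohort)
        expected = {
            cohort.marker_names[j]
            for j in range(4)
            if abs(_skew_oracle(X[:, j])) > 1.0
        }
        assert transformed == expected

    def test_nonpositive_value_in_selected_marker_errors(self, rng):
        x = np.exp(rng.normal(0, 1, 500))
        x[3] = 0.0
        cohort = make_cohort(x[:, None])
        with pytest.raises(CohortError, match="m00"):
            normal_transform(cohort)


class TestZscore:
    def test_small_example(self):
        cohort = make_cohort(np.array([[1.0], [2.0], [3.0]]))
        out, _ = zscore_normalize(cohort)
        np.testing.assert_allclose(out.markers[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent_on_standardized_data(self, rng):
        x = rng.normal(size=(200, 3))
        out1, _ = zscore_normalize(make_cohort(x))
        out2, _ = zscore_normalize(out1)
        np.testing.assert_allclose(out1.markers, out2.markers, atol=1e-10)

    def test_heterogeneous_units_standardized(self, rng):
        X = rng.normal(0, 1, (300, 4)) * [0.1, 5, 200, 1e4] + [1, -3, 500, 2e5]
        out, _ = zscore_normalize(make_cohort(X))
        np.testing.assert_allclose(out.markers.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.markers.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_round_trip(self, rng):
        X = rng.normal(3, 7, (100, 3))
        out, (means, sds) = zscore_normalize(make_cohort(X))
        np.testing.assert_allclose(out.markers * sds + means, X, atol=1e-8)

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateMarkerError):
            zscore_normalize(make_cohort(np.ones((10, 1))))

    def test_frozen_params_reapplied(self, rng):
        X = rng.normal(5, 2, (100, 2))
        _, params = zscore_normalize(make_cohort(X))
        Y = rng.normal(5, 2, (50, 2))
        out, _ = zscore_normalize(make_cohort(Y), params=params)
        np.testing.assert_allclose(out.markers, (Y - params[0]) / params[1], atol=1e-12)


class TestAgeAdjust:
    def test_null_marker_unchanged(self, rng):
        ages = rng.uniform(20, 85, 500)
        X = rng.normal(0, 1, (500, 1))
        out, model = age_adjust(make_cohort(X, ages=ages))
        assert not model.gated[0]
        np.testing.assert_array_equal(out.markers, X)

    def test_perfect_linear_marker_becomes_constant_mean(self):
        ages = np.linspace(20, 70, 100)
        X = (2.0 * ages)[:, None]
        out, model = age_adjust(make_cohort(X, ages=ages))
        assert model.gated[0]
        np.testing.assert_allclose(out.markers[:, 0], X.mean(), atol=1e-8)

    def test_planted_slope_recovered_and_decorrelated(self, rng):
        n = 2000
        ages = rng.uniform(20, 85, n)
        X = (0.5 * ages + rng.normal(0, 1, n))[:, None]
        out, model = age_adjust(make_cohort(X, ages=ages))
        assert model.gated[0]
        assert model.slope[0] == pytest.approx(0.5, abs=0.01)
        r = np.corrcoef(out.markers[:, 0], ages)[0, 1]
        assert abs(r) < 0.05
        # exact residual orthogonality on the fitting sample
        assert abs(r) < 1e-10

    def test_mean_preserved(self, rng):
        n = 500
        ages = rng.uniform(20, 85, n)
        X = (0.3 * ages + rng.normal(10, 2, n))[:, None]
        out, model = age_adjust(make_cohort(X, ages=ages))
        assert out.markers[:, 0].mean() == pytest.approx(X[:, 0].mean(), abs=1e-10)

    def test_constant_ages_error(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(CohortError):
            age_adjust(make_cohort(X, ages=np.full(50, 40.0)))

    def test_gate_thresholds(self, rng):
        # r just below 0.1 must not gate even when p < 0.05
        n = 4000
        ages = rng.uniform(20, 85, n)
        sd_age = np.std(ages)
        for target_r, expect in ((0.05, False), (0.3, True)):
            slope = target_r / np.sqrt(1 - target_r**2) / sd_age
            x = slope * ages + rng.normal(0, 1, n)
            _, model = age_adjust(make_cohort(x[:, None], ages=ages))
            assert bool(model.gated[0]) is expect, f"target r={target_r}"


class TestMissing:
    def test_complete_cases_drops_and_logs_ids(self, rng):
        X = rng.normal(size=(10, 3))
        mask = np.zeros_like(X, bool)
        mask[2, 1] = True
        mask[7, 0] = True
        cohort = make_cohort(X, mask=mask)
        out, dropped = complete_cases(cohort)
        assert out.n_samples == 8
        assert set(dropped) == {"s0002", "s0007"}

    def test_impute_median(self, rng):
        X = rng.normal(size=(11, 2))
        mask = np.zeros_like(X, bool)
        mask[5, 0] = True
        out = impute_median(make_cohort(X, mask=mask))
        expected = np.median(np.delete(X[:, 0], 5))
        assert out.markers[5, 0] == pytest.approx(expected)
        assert not out.has_missing()


class TestPreprocessVariants:
    def test_raw_is_identity(self, rng):
        X = rng.normal(size=(50, 4))
        cohort = make_cohort(X)
        out, rec = preprocess(cohort, "raw")
        np.testing.assert_array_equal(out.markers, X)
        assert rec.variant is PipelineVariant.RAW

    def test_age_adjust_zscore_equals_zscore_when_no_age_effect(self, rng):
        ages = rng.uniform(20, 85, 800)
        X = rng.normal(0, 1, (800, 5))
        cohort = make_cohort(X, ages=ages)
        a, _ = preprocess(cohort, "age_adjust_zscore")
        b, _ = preprocess(cohort, "zscore")
        np.testing.assert_allclose(a.markers, b.markers, atol=1e-10)

    def test_aggregate_transforms_chains_log(self, rng):
        X = np.column_stack([np.exp(rng.normal(0, 1.2, 600)), rng.normal(5, 1, 600)])
        cohort = make_cohort(X)
        out, rec = preprocess(cohort, "zscore", aggregate_transforms=True)
        assert rec.log_transformed == {"m00"}
        np.testing.assert_allclose(out.markers.mean(axis=0), 0.0, atol=1e-10)

    def test_invalid_variant_rejected(self, rng):
        with pytest.raises(ValueError):
            preprocess(make_cohort(rng.normal(size=(5, 3))), "bogus")

    def test_missing_policy_applied_before_transform(self, rng):
        X = rng.normal(size=(30, 3))
        mask = np.zeros_like(X, bool)
        mask[0, 0] = True
        out, rec = preprocess(make_cohort(X, mask=mask), "zscore")
        assert out.n_samples == 29
        assert rec.dropped_ids == ["s0000"]
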