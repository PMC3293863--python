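import numpy as np
import pytest

from cohortcluster.cohort import Clustering, CohortError, pearson_vec
from cohortcluster.quality import (
    QualitySummary,
    cluster_quality,
    compare_quality,
    quality_resample,
)
from cohortcluster.synth import generate_cohort_pair, separated_spec

from .conftest import make_cohort


def quality_oracle(X, labels):
    """Naive double-loop recomputation of H_A and S_A from their definitions."""
    labs = sorted(set(labels) - {0})
    cents = {k: X[np.array(labels) == k].mean(axis=0) for k in labs}
    sims = []
    for i, lab in enumerate(labels):
        if lab == 0:
            continue
        sims.append(pearson_vec(X[i], cents[lab]))
    H = float(np.mean(sims))
    if len(labs) == 1:
        return H, 0.0
    num = den = 0.0
    for a in range(len(labs)):
        for b in range(a + 1, len(labs)):
            na = np.sum(np.array(labels) == labs[a])
            nb = np.sum(np.array(labels) == labs[b])
            num += na * nb * pearson_vec(cents[labs[a]], cents[labs[b]])
            den += na * nb
    return H, float(num / den)


def _clustering(cohort, labels):
    return Clustering(cohort.sample_ids, np.asarray(labels, int))


class TestClusterQuality:
    def test_single_cluster_convention(self, rng):
        cohort = make_cohort(rng.normal(size=(10, 5)))
        H, S, diff = cluster_quality(cohort, _clustering(cohort, np.ones(10)))
        assert S == 0.0
        assert diff == H

    def test_antipodal_construction(self):
        c1 = np.array([1.0, 0.0, -1.0])
        c2 = -c1
        X = np.vstack([c1, c1, c2, c2])
        cohort = make_cohort(X)
        H, S, diff = cluster_quality(cohort, _clustering(cohort, [1, 1, 2, 2]))
        assert H == pytest.approx(1.0, abs=1e-12)
        assert S == pytest.approx(-1.0, abs=1e-12)
        assert diff == pytest.approx(2.0, abs=1e-12)

    def test_agrees_with_oracle_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 50))
            p = int(rng.integers(3, 8))
            X = rng.normal(size=(n, p))
            k = int(rng.integers(1, 4))
            labels = rng.integers(1, k + 1, n)
            labels[: k + 1] = np.arange(1, k + 2)[: len(labels[: k + 1])] % (k + 1)
            labels[labels == 0] = 1
            cohort = make_cohort(X)
            H, S, _ = cluster_quality(cohort, _clustering(cohort, labels))
            Ho, So = quality_oracle(X, labels)
            assert H == pytest.approx(Ho, abs=1e-10)
            assert S == pytest.approx(So, abs=1e-10)

    def test_unclassified_excluded(self, rng):
        X = rng.normal(size=(20, 5))
        cohort = make_cohort(X)
        labels = np.array([1] * 9 + [2] * 9 + [0, 0])
        H, S, _ = cluster_quality(cohort, _clustering(cohort, labels))
        Ho, So = quality_oracle(X, labels)
        assert H == pytest.approx(Ho, abs=1e-12)
        assert S == pytest.approx(So, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        X = rng.normal(size=(30, 5))
        cohort = make_cohort(X)
        labels = rng.integers(1, 4, 30)
        _, _, d1 = cluster_quality(cohort, _clustering(cohort, labels))
        permuted = np.array([{1: 3, 2: 1, 3: 2}[l] for l in labels])
        _, _, d2 = cluster_quality(cohort, _clustering(cohort, permuted))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(30, 5))
        labels = rng.integers(1, 4, 30)
        perm = rng.permutation(30)
        c1 = make_cohort(X)
        c2 = make_cohort(X[perm])
        _, _, d1 = cluster_quality(c1, _clustering(c1, labels))
        _, _, d2 = cluster_quality(c2, _clustering(c2, labels[perm]))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_constant_centroid_errors(self):
        X = np.vstack([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        cohort = make_cohort(X)
        with pytest.raises(CohortError, match="cluster 1"):
            cluster_quality(cohort, _clustering(cohort, [1, 1, 2]))

    def test_id_mismatch_errors(self, rng):
        c1 = make_cohort(rng.normal(size=(5, 4)))
        other = Clustering(np.array(["x1", "x2", "x3", "x4", "x5"]), np.ones(5, int))
        with pytest.raises(CohortError):
            cluster_quality(c1, other)


class TestQualityResample:
    def _spec(self, seed=3):
        return separated_spec(n_subgroups=3, n_train=200, n_valid=50,
                              n_markers=8, n_informative=8, separation=6.0,
                              seed=seed)

    def test_frac_zero_reproduces_full_run(self):
        train, *_ = generate_cohort_pair(self._spec())
        s = quality_resample(train, "zscore", "kmeans", frac=0.0, n_reps=1,
                             seed=0, k=3)
        assert s.mean_diff == s.diff
        assert s.resampled[0][1] == s.K

    def test_easy_problem_is_stable(self):
        train, *_ = generate_cohort_pair(self._spec())
        s = quality_resample(train, "zscore", "kmeans", frac=0.03, n_reps=10,
                             seed=1, k=3)
        assert s.sd_diff < 0.05
        assert len(s.resampled) == 10

    def test_determinism(self):
        train, *_ = generate_cohort_pair(self._spec())
        a = quality_resample(train, "zscore", "kmeans", n_reps=5, seed=9, k=3)
        b = quality_resample(train, "zscore", "kmeans", n_reps=5, seed=9, k=3)
        assert a.resampled == b.resampled

    def test_invalid_frac_rejected(self):
        train, *_ = generate_cohort_pair(self._spec())
        with pytest.raises(ValueError):
            quality_resample(train, "zscore", "kmeans", frac=1.0, k=3)

    def test_separation_monotone_trend(self):
        means = []
        for sep in (2.0, 4.0, 6.0):
            spec = separated_spec(n_subgroups=3, n_train=200, n_valid=50,
                                  n_markers=8, n_informative=8,
                                  separation=sep, seed=13)
            train, *_ = generate_cohort_pair(spec)
            s = quality_resample(train, "zscore", "kmeans", n_reps=5, seed=2, k=3)
            means.append(s.mean_diff)
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9


class TestCompareQuality:
    @staticmethod
    def _summary(diffs):
        diffs = list(diffs)
        return QualitySummary(H_A=0, S_A=0, diff=diffs[0], K=2,
                              resampled=[(d, 2) for d in diffs])

    def test_identical_lists(self):
        a = self._summary([0.5, 0.5, 0.5])
        t, p = compare_quality(a, a)
        assert t == 0.0
        assert p == 1.0

    def test_strong_difference(self, rng):
        a = self._summary(0.55 + 0.01 * rng.standard_normal(10))
        b = self._summary(0.05 + 0.01 * rng.standard_normal(10))
        t, p = compare_quality(a, b)
        assert p < 1e-6
        assert t > 0

    def test_matches_closed_form(self):
        xa = [0.1, 0.2, 0.3]
        xb = [0.4, 0.5, 0.6]
        t, p = compare_quality(self._summary(xa), self._summary(xb))
        # classical pooled-variance two-sample t with 4 df
        from scipy import stats
        sp2 = (np.var(xa, ddof=1) * 2 + np.var(xb, ddof=1) * 2) / 4
        t_expected = (np.mean(xa) - np.mean(xb)) / np.sqrt(sp2 * (2 / 3))
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_expected), 4), rel=1e-12)

    def test_type_one_error_rate(self, rng):
        hits = 0
        for _ in range(100):
            a = self._summary(0.3 + 0.01 * rng.standard_normal(10))
            b = self._summary(0.3 + 0.01 * rng.standard_normal(10))
            _, p = compare_quality(a, b)
            hits += p > 0.05
        assert hits >= 90

    def test_zero_variance_unequal_means(self):
        a = self._summary([0.5, 0.5])
        b = self._summary([0.1, 0.1])
        t, p = compare_quality(a, b)
        assert p == 0.0
        assert np.isinf(t)

    def test_too_few_values_rejected(self):
        a = self._summary([0.5])
        with pytest.raises(ValueError):
            compare_quality(a, a)
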