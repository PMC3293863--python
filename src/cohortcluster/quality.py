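"""Homogeneity / separation cluster validity scoring.

``H_A`` is the mean Pearson similarity between each clustered sample and its
cluster centroid; ``S_A`` is the size-weighted mean similarity between
centroids of different clusters:

    S_A = sum_{i<j} n_i n_j sim(c_i, c_j) / sum_{i<j} n_i n_j

The package's single-number score is ``H_A - S_A`` (higher = compact and
well separated).  Unclassified samples are excluded from both statistics and
a single-cluster solution has ``S_A = 0`` by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cluster import ClickParams, run_algorithm
from .cohort import Clustering, CohortError, CohortMatrix, pearson_vec
from .preprocess import PipelineVariant, preprocess


def cluster_quality(
    cohort: CohortMatrix, clustering: Clustering
) -> tuple[float, float, float]:
    """Return ``(H_A, S_A, H_A - S_A)`` for a clustering of ``cohort``."""
    if not np.array_equal(cohort.sample_ids, clustering.sample_ids):
        raise CohortError("clustering ids do not match cohort ids")
    X = np.asarray(cohort.markers, float)
    labels_used = clustering.cluster_labels
    K = len(labels_used)
    if K < 1:
        raise CohortError("clustering has no clusters")

    centroids = np.empty((K, cohort.n_markers))
    sizes = np.empty(K)
    for a, k in enumerate(labels_used):
        mem = clustering.members(k)
        centroids[a] = X[mem].mean(axis=0)
        sizes[a] = mem.size

    sims = []
    for a, k in enumerate(labels_used):
        cen = centroids[a]
        if np.std(cen) == 0:
            raise CohortError(f"cluster {k} has a constant centroid profile")
        for i in clustering.members(k):
            sims.append(pearson_vec(X[i], cen))
    H = float(np.mean(sims))

    if K == 1:
        S = 0.0
    else:
        num = 0.0
        den = 0.0
        for a in range(K):
            for b in range(a + 1, K):
                w = sizes[a] * sizes[b]
                num += w * pearson_vec(centroids[a], centroids[b])
                den += w
        S = float(num / den)
    return H, S, H - S


@dataclass
class QualitySummary:
    """Full-data score plus the dropout-resampling distribution."""

    H_A: float
    S_A: float
    diff: float
    K: int
    resampled: list[tuple[float, int]] = field(default_factory=list)

    @property
    def diffs(self) -> np.ndarray:
        return np.array([d for d, _ in self.resampled])

    @property
    def ks(self) -> np.ndarray:
        return np.array([k for _, k in self.resampled])

    @property
    def mean_diff(self) -> float:
        return float(self.diffs.mean()) if self.resampled else self.diff

    @property
    def sd_diff(self) -> float:
        return float(self.diffs.std(ddof=1)) if len(self.resampled) > 1 else 0.0

    @property
    def mean_K(self) -> float:
        return float(self.ks.mean()) if self.resampled else float(self.K)

    @property
    def sd_K(self) -> float:
        return float(self.ks.std(ddof=1)) if len(self.resampled) > 1 else 0.0


def quality_resample(
    cohort: CohortMatrix,
    variant: PipelineVariant | str,
    algorithm: str,
    *,
    frac: float = 0.03,
    n_reps: int = 10,
    seed: int = 0,
    k: int | None = None,
    click_params: ClickParams | None = None,
    aggregate_transforms: bool = False,
    missing: str = "complete",
) -> QualitySummary:
    """Dropout-resampled quality for one preprocessing x algorithm pipeline.

    Each repetition removes ``floor(frac * n)`` samples uniformly at random
    from the *raw* cohort, reruns preprocess -> cluster -> score, and
    collects ``(H_A - S_A, K)``.  ``k`` fixes the cluster count for
    kmeans/som (by convention, the full-data CLICK count of the same
    variant).
    """
    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must be in [0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    def one_run(sub: CohortMatrix, run_seed: int) -> tuple[float, int]:
        pre, _ = preprocess(sub, variant, aggregate_transforms=aggregate_transforms,
                            missing=missing)
        cl = run_algorithm(pre, algorithm, k=k, click_params=click_params, seed=run_seed)
        _, _, d = cluster_quality(pre, cl)
        return d, cl.n_clusters

    full_pre, _ = preprocess(cohort, variant, aggregate_transforms=aggregate_transforms,
                             missing=missing)
    full_cl = run_algorithm(full_pre, algorithm, k=k, click_params=click_params,
                            seed=int(seed))
    H, S, diff = cluster_quality(full_pre, full_cl)

    n = cohort.n_samples
    n_drop = int(np.floor(frac * n))
    resampled: list[tuple[float, int]] = []
    ss = np.random.SeedSequence(int(seed))
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        if n_drop:
            drop = rng.choice(n, size=n_drop, replace=False)
            keep = np.setdiff1d(np.arange(n), drop)
            sub = cohort.take(keep)
        else:
            sub = cohort
        # clustering seed is held fixed so frac=0 reproduces the full run
        resampled.append(one_run(sub, run_seed=int(seed)))
    return QualitySummary(H, S, diff, full_cl.n_clusters, resampled)


def compare_quality(
    a: QualitySummary, b: QualitySummary, *, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t-test on the resampled ``H_A - S_A`` lists (two-sided).

    Equal-variance Student's t by default; set ``welch=True`` for Welch.
    """
    xa, xb = a.diffs, b.diffs
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("compare_quality needs >= 2 resampled values per side")
    if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0:
        if np.isclose(xa.mean(), xb.mean()):
            return 0.0, 1.0
        return float(np.inf if xa.mean() > xb.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    return float(t), float(p)
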