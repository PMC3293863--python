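"""The three clustering algorithms of the experiment grid.

* :func:`click_cluster` — a CLICK-style graph clustering: pairwise Pearson
  similarities are modeled as a two-component ("mates" / "non-mates") normal
  mixture fitted by EM, edges are weighted by the log likelihood ratio,
  non-positive edges are dropped, components are recursively split by global
  minimum-weight cuts until homogeneous kernels remain, then singleton
  adoption and kernel merging run.  Samples left over are UNCLASSIFIED.
* :func:`kmeans_cluster` — Lloyd iterations with k-means++ seeding, best of
  R restarts (scikit-learn backend).
* :func:`som_cluster` — batch self-organizing map on a near-square grid;
  each non-empty cell is a cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from ._mincut import min_cut
from .cohort import Clustering, CohortError, CohortMatrix, pearson_rows

log = logging.getLogger(__name__)

_EM_MAX_PAIRS = 200_000  # deterministic stride subsample for mixture fitting


@dataclass
class ClickParams:
    """Tuning knobs of the graph clustering.

    Thresholds left as ``None`` are derived from the fitted similarity
    mixture: homogeneity/adoption default to the mates vs non-mates crossing
    point, the merge threshold to the mates-component mean.
    """

    homogeneity: float | None = None
    min_kernel_size: int = 5
    adoption: float | None = None
    merge: float | None = None
    em_max_iter: int = 200
    em_tol: float = 1e-8
    adoption_passes: int = 3
    refine_passes: int = 3
    metric: str = "pearson"  # or "rbf" (Gaussian kernel on Euclidean distance)
    batch_peel: bool = True
    max_degree: int = 25  # mutual top-m sparsification of the mate graph
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("homogeneity", "adoption", "merge"):
            v = getattr(self, name)
            if v is not None and not -1.0 < v < 1.0:
                raise ValueError(f"{name} threshold must lie in (-1, 1)")
        if self.min_kernel_size < 2:
            raise ValueError("min kernel size must be >= 2")


@dataclass
class _Mixture:
    prob_mates: float
    mu0: float
    sd0: float
    mu1: float
    sd1: float
    crossing: float  # similarity where the edge weight changes sign
    mates_mean: float
    em_ok: bool

    def weight(self, s: np.ndarray) -> np.ndarray:
        if not self.em_ok:
            return s - self.crossing
        p = self.prob_mates
        w = (
            math.log(p / (1.0 - p))
            + _norm_logpdf(s, self.mu1, self.sd1)
            - _norm_logpdf(s, self.mu0, self.sd0)
        )
        return w


def _norm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def _fit_similarity_mixture(s: np.ndarray, params: ClickParams) -> _Mixture:
    """Two-component 1-D normal mixture by EM; component 1 = mates."""
    s = np.asarray(s, float)
    if s.size > _EM_MAX_PAIRS:
        step = s.size // _EM_MAX_PAIRS + 1
        s = s[::step]
    spread = float(np.std(s))
    mean = float(np.mean(s))
    if spread < 1e-12:
        return _Mixture(0.5, mean, 1.0, mean, 1.0, mean, mean, em_ok=False)

    q75 = np.quantile(s, 0.75)
    hi = s >= q75
    mu1, mu0 = float(s[hi].mean()), float(s[~hi].mean())
    sd1 = float(max(s[hi].std(), 1e-3 * spread))
    sd0 = float(max(s[~hi].std(), 1e-3 * spread))
    p = 0.25
    ll_prev = -np.inf
    for _ in range(params.em_max_iter):
        l1 = np.log(p) + _norm_logpdf(s, mu1, sd1)
        l0 = np.log1p(-p) + _norm_logpdf(s, mu0, sd0)
        mx = np.maximum(l1, l0)
        denom = mx + np.log(np.exp(l1 - mx) + np.exp(l0 - mx))
        r1 = np.exp(l1 - denom)
        ll = float(denom.sum())
        w1 = r1.sum()
        w0 = s.size - w1
        if w1 < 2 or w0 < 2:
            break
        p = float(w1 / s.size)
        mu1 = float((r1 * s).sum() / w1)
        mu0 = float(((1 - r1) * s).sum() / w0)
        sd1 = float(max(np.sqrt((r1 * (s - mu1) ** 2).sum() / w1), 1e-3 * spread))
        sd0 = float(max(np.sqrt(((1 - r1) * (s - mu0) ** 2).sum() / w0), 1e-3 * spread))
        if abs(ll - ll_prev) < params.em_tol * max(1.0, abs(ll)):
            break
        ll_prev = ll
    if mu1 < mu0:  # keep component 1 = higher-similarity mates
        mu0, mu1, sd0, sd1, p = mu1, mu0, sd1, sd0, 1.0 - p
    # judge separation from the fitted parameters, not EM convergence speed
    separated = (mu1 - mu0) > 0.05 * spread and 1e-6 < p < 1.0 - 1e-6
    if not separated:
        cutoff = mean + 0.5 * spread
        log.info("similarity mixture EM failed to separate; fixed cutoff %.3f", cutoff)
        mates_mean = float(s[s > cutoff].mean()) if np.any(s > cutoff) else cutoff
        return _Mixture(0.5, mean, spread, mean, spread, cutoff, mates_mean, em_ok=False)

    mix = _Mixture(p, mu0, sd0, mu1, sd1, 0.0, mu1, em_ok=True)
    lo_w = mix.weight(np.array([mu0]))[0]
    hi_w = mix.weight(np.array([mu1]))[0]
    if lo_w >= 0 or hi_w <= 0:
        mix.crossing = 0.5 * (mu0 + mu1)
    else:  # bisect the sign change between the component means
        lo, hi2 = mu0, mu1
        for _ in range(80):
            mid = 0.5 * (lo + hi2)
            if mix.weight(np.array([mid]))[0] > 0:
                hi2 = mid
            else:
                lo = mid
        mix.crossing = 0.5 * (lo + hi2)
    return mix


def _similarity_matrix(X: np.ndarray, metric: str) -> tuple[np.ndarray, float | None]:
    """Pairwise similarity and (for rbf) the fitted bandwidth."""
    if metric == "pearson":
        return pearson_rows(X), None
    if metric == "rbf":
        sq = np.sum(X**2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
        med = np.median(d2[np.triu_indices_from(d2, 1)])
        med = med if med > 0 else 1.0
        bw = med / 4.0  # tighter than the median heuristic: spreads the
        return np.exp(-d2 / (2.0 * bw)), bw  # mate/non-mate modes apart
    raise ValueError(f"unknown similarity metric {metric!r}")


def _sims_to_rows(X: np.ndarray, C: np.ndarray, metric: str,
                  bandwidth: float | None) -> np.ndarray:
    """Similarity of every row of ``X`` to every row of ``C`` in the same
    metric (and bandwidth) as the pairwise matrix."""
    if metric == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        Cc = C - C.mean(axis=1, keepdims=True)
        xn = np.linalg.norm(Xc, axis=1)
        cn = np.linalg.norm(Cc, axis=1)
        if np.any(xn == 0) or np.any(cn == 0):
            raise CohortError("constant profile in similarity computation")
        return np.clip((Xc / xn[:, None]) @ (Cc / cn[:, None]).T, -1.0, 1.0)
    d2 = np.maximum(
        np.sum(X**2, axis=1)[:, None] + np.sum(C**2, axis=1)[None, :]
        - 2.0 * X @ C.T, 0.0)
    return np.exp(-d2 / (2.0 * (bandwidth or 1.0)))


def _spectral_side(W: np.ndarray) -> np.ndarray:
    """Sign split along the dominant eigenvector of a symmetric weight
    matrix (deterministic power iteration; shifted to dominate in modulus).

    The off-diagonal mean is removed first: without centering, an
    all-positive weight matrix has a Perron eigenvector with uniform signs
    and the split would be arbitrary; after centering the partition
    structure carries the leading eigenvector.
    """
    m = W.shape[0]
    W = W - float((W.sum() - np.trace(W)) / max(m * (m - 1), 1))
    np.fill_diagonal(W, 0.0)
    # shift so the largest-|lambda| eigenvalue is the algebraically largest
    shift = float(np.abs(W).sum(axis=1).max()) + 1.0
    v = np.full(m, 1.0 / math.sqrt(m))
    for _ in range(100):
        nv = W @ v + shift * v
        norm = np.linalg.norm(nv)
        if norm == 0:
            break
        nv /= norm
        if np.linalg.norm(nv - v) < 1e-10:
            v = nv
            break
        v = nv
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    side = v >= np.median(v) if np.all(v >= 0) or np.all(v <= 0) else v >= 0
    if side.all() or not side.any():  # defensive: force a proper bipartition
        side = np.zeros(m, dtype=bool)
        side[: m // 2] = True
    return side


def _mean_offdiag(S: np.ndarray, idx: np.ndarray) -> float:
    m = idx.size
    sub = S[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def click_cluster(cohort: CohortMatrix, params: ClickParams | None = None) -> Clustering:
    """Graph clustering that may leave samples UNCLASSIFIED (see module docs)."""
    params = params or ClickParams()
    X = np.asarray(cohort.markers, float)
    n = X.shape[0]
    if n < params.min_kernel_size:
        raise CohortError("fewer samples than the minimum kernel size")
    S, bandwidth = _similarity_matrix(X, params.metric)
    iu = np.triu_indices(n, 1)
    sims = S[iu]

    # near-degenerate input: everything is everyone's mate
    if sims.min() >= 1.0 - 1e-6:
        return Clustering(cohort.sample_ids, np.ones(n, dtype=int),
                          provenance=_prov("click", params, n_clusters=1))

    mix = _fit_similarity_mixture(sims, params)
    Wfull = mix.weight(S)  # log likelihood ratios; negative = non-mate evidence
    np.fill_diagonal(Wfull, 0.0)
    Wpos = np.where(Wfull > 0, Wfull, 0.0)
    if params.max_degree and n > params.max_degree + 1:
        # mutual top-m sparsification: a vanishing per-pair false-mate rate
        # still yields O(n^2) spurious cross-cluster edges, which would fuse
        # distinct clusters into one component; keeping only reciprocal
        # strongest edges removes them while dense clusters stay connected
        m = params.max_degree
        order = np.argpartition(-Wpos, m, axis=1)[:, :m]
        keep = np.zeros_like(Wpos, dtype=bool)
        np.put_along_axis(keep, order, True, axis=1)
        Wpos = np.where(keep & keep.T, Wpos, 0.0)

    a_thresh = params.adoption if params.adoption is not None else mix.crossing
    m_thresh = params.merge if params.merge is not None else mix.mates_mean

    kernels: list[np.ndarray] = []
    pool: list[int] = []
    n_comp, comp_labels = connected_components(csr_matrix(Wpos > 0), directed=False)
    stack = [np.flatnonzero(comp_labels == c) for c in range(n_comp)]
    stack.reverse()  # process lowest component label first
    while stack:
        idx = stack.pop()
        if idx.size < params.min_kernel_size:
            pool.extend(int(i) for i in idx)
            continue
        Wf_sub = Wfull[np.ix_(idx, idx)]
        if params.homogeneity is not None:
            # explicit absolute gate replaces the cut-positivity criterion
            if _mean_offdiag(S, idx) >= params.homogeneity:
                kernels.append(idx)
                continue
            side = _spectral_side(Wf_sub)
        elif _mean_offdiag(Wfull, idx) > 0.0:
            # mates-dominated component: candidate kernel.  Kernel test: the
            # candidate cheapest cuts (global min cut of the positive
            # subgraph, plus the spectral bipartition), scored with the full
            # weights (negative non-mate edges included), must be positive.
            Wsub = Wpos[np.ix_(idx, idx)]
            cut_w, side = min_cut(Wsub)
            full_cut = float(Wf_sub[side][:, ~side].sum())
            sp_side = _spectral_side(Wf_sub)
            sp_cut = float(Wf_sub[sp_side][:, ~sp_side].sum())
            if full_cut > 0 and sp_cut > 0:
                kernels.append(idx)
                continue
            if sp_cut < full_cut:
                side = sp_side
            else:
                small = min(side.sum(), idx.size - side.sum())
                if params.batch_peel and small == 1 and idx.size > 20:
                    # the min cut peeled a single weakly attached vertex;
                    # peel every vertex as weakly attached in one pass (each
                    # would be split off by an equally cheap cut anyway)
                    deg = Wsub.sum(axis=0)
                    weak = deg <= cut_w + 1e-12
                    if 1 < weak.sum() < idx.size:
                        side = weak
        else:
            # non-mate evidence dominates: a global min cut of the positive
            # subgraph degenerates to singleton peeling here (cross-cluster
            # edge mass grows ~n^2), so split along the dominant eigenvector
            # of the full weight matrix instead
            side = _spectral_side(Wf_sub)
        part_a, part_b = idx[side], idx[~side]
        # re-derive connected components inside each shore before recursing
        for part in (part_b, part_a):
            if part.size == 0:
                continue
            if part.size == 1:
                stack.append(part)
                continue
            sub = Wpos[np.ix_(part, part)] > 0
            nc, cl = connected_components(csr_matrix(sub), directed=False)
            for c in range(nc - 1, -1, -1):
                stack.append(part[cl == c])

    for ker in kernels:
        assert ker.size >= params.min_kernel_size

    # adoption: attach leftover samples to their most similar kernel
    members = [list(map(int, k)) for k in kernels]
    for _ in range(params.adoption_passes):
        if not pool or not members:
            break
        adopted_now: list[tuple[int, int]] = []
        remaining: list[int] = []
        for i in sorted(pool):
            best_k, best_s = -1, -np.inf
            for kidx, mem in enumerate(members):
                avg = float(S[i, mem].mean())
                if avg > best_s:
                    best_k, best_s = kidx, avg
            if best_s >= a_thresh:
                adopted_now.append((i, best_k))
            else:
                remaining.append(i)
        if not adopted_now:
            break
        for i, kidx in adopted_now:
            members[kidx].append(i)
        pool = remaining

    # merge kernels whose marker-space centroids are near-identical profiles
    if cohort.n_markers >= 3:
        merged = True
        while merged and len(members) > 1:
            merged = False
            cents = np.array([X[m].mean(axis=0) for m in members])
            try:
                C = _sims_to_rows(cents, cents, params.metric, bandwidth)
            except CohortError:
                break
            np.fill_diagonal(C, -np.inf)
            a, b = np.unravel_index(int(np.argmax(C)), C.shape)
            if C[a, b] >= m_thresh:
                lo, hi = min(a, b), max(a, b)
                members[lo] = sorted(members[lo] + members[hi])
                del members[hi]
                merged = True

    # refinement: reassign every sample to its most similar cluster centroid
    # (kernel boundaries from recursive splitting are noisy); samples whose
    # best centroid similarity falls below the adoption threshold unclassify
    for _ in range(params.refine_passes):
        members = [m for m in members if m]
        if not members:
            break
        cents = np.array([X[m].mean(axis=0) for m in members])
        try:
            sim_to_cent = _sims_to_rows(X, cents, params.metric, bandwidth)
        except CohortError:
            break
        best = np.argmax(sim_to_cent, axis=1)
        best_sim = sim_to_cent[np.arange(n), best]
        new_members: list[list[int]] = [[] for _ in members]
        new_pool: list[int] = []
        for i in range(n):
            if best_sim[i] >= a_thresh:
                new_members[best[i]].append(i)
            else:
                new_pool.append(i)
        if [sorted(m) for m in new_members] == [sorted(m) for m in members]:
            break
        members, pool = new_members, new_pool
    members = [m for m in members if m]

    labels = np.zeros(n, dtype=int)
    order = sorted(range(len(members)), key=lambda k: min(members[k]) if members[k] else n)
    lab = 1
    for k in order:
        if not members[k]:
            continue
        labels[members[k]] = lab
        lab += 1
    return Clustering(
        cohort.sample_ids,
        labels,
        provenance=_prov("click", params, n_clusters=lab - 1,
                         em_ok=mix.em_ok, crossing=round(mix.crossing, 6)),
    )


def _prov(algorithm: str, params, **extra) -> dict:
    d = {"algorithm": algorithm, "params": repr(params)}
    d.update(extra)
    return d


def kmeans_cluster(
    cohort: CohortMatrix, k: int, seed: int = 0, *, restarts: int = 10
) -> Clustering:
    """K-means with k-means++ seeding, best inertia over ``restarts``."""
    n = cohort.n_samples
    if not 1 <= k <= n:
        raise CohortError(f"k={k} outside 1..{n}")
    km = KMeans(n_clusters=int(k), n_init=int(restarts), random_state=int(seed))
    raw = km.fit_predict(np.asarray(cohort.markers, float))
    # relabel to dense 1..K by first appearance for determinism
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[i] = mapping[lab]
    return Clustering(cohort.sample_ids, labels,
                      provenance=_prov("kmeans", {"k": k, "restarts": restarts, "seed": seed}))


def _grid_shape(n_cells: int) -> tuple[int, int]:
    """Factorization rows x cols of n_cells closest to square (rows <= cols)."""
    best = (1, n_cells)
    for r in range(1, int(math.isqrt(n_cells)) + 1):
        if n_cells % r == 0:
            best = (r, n_cells // r)
    return best


def som_cluster(
    cohort: CohortMatrix,
    n_cells: int,
    seed: int = 0,
    *,
    epochs: int = 50,
) -> Clustering:
    """Batch self-organizing map; every non-empty cell becomes a cluster.

    The neighborhood is Gaussian over grid distance with radius shrinking
    linearly from ``max(rows, cols) / 2`` to 0.5 over the epochs.
    """
    if n_cells < 1:
        raise CohortError("n_cells must be >= 1")
    X = np.asarray(cohort.markers, float)
    n = X.shape[0]
    if n_cells > n:
        log.warning("SOM has more cells (%d) than samples (%d); empty cells dropped",
                    n_cells, n)
    rows, cols = _grid_shape(n_cells)
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    rng = np.random.default_rng(int(seed))
    init_idx = rng.choice(n, size=n_cells, replace=n_cells > n)
    protos = X[init_idx].astype(float).copy()

    r0 = max(rows, cols) / 2.0
    r1 = 0.5
    for t in range(epochs):
        radius = r0 + (r1 - r0) * (t / max(epochs - 1, 1))
        d2 = ((X[:, None, :] - protos[None, :, :]) ** 2).sum(-1)
        bmu = np.argmin(d2, axis=1)
        H = np.exp(-grid_d2 / (2.0 * radius * radius))  # cells x cells
        G = H[bmu]  # samples x cells
        denom = G.sum(axis=0)
        numer = G.T @ X
        upd = denom > 1e-12
        protos[upd] = numer[upd] / denom[upd, None]

    d2 = ((X[:, None, :] - protos[None, :, :]) ** 2).sum(-1)
    bmu = np.argmin(d2, axis=1)
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for cell in range(n_cells):  # label non-empty cells in grid order
        if np.any(bmu == cell):
            mapping[cell] = len(mapping) + 1
    for i, cell in enumerate(bmu):
        labels[i] = mapping[cell]
    return Clustering(
        cohort.sample_ids,
        labels,
        provenance=_prov("som", {"n_cells": n_cells, "epochs": epochs, "seed": seed},
                         grid=(rows, cols)),
    )


def run_algorithm(
    cohort: CohortMatrix,
    algorithm: str,
    *,
    k: int | None = None,
    click_params: ClickParams | None = None,
    seed: int = 0,
) -> Clustering:
    """Dispatch helper used by resampling and the experiment driver."""
    if algorithm == "click":
        return click_cluster(cohort, click_params)
    if k is None:
        raise CohortError(f"algorithm {algorithm!r} needs a cluster count k")
    if algorithm == "kmeans":
        return kmeans_cluster(cohort, k, seed=seed)
    if algorithm == "som":
        return som_cluster(cohort, k, seed=seed)
    raise CohortError(f"unknown algorithm {algorithm!r}")
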