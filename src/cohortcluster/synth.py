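"""Synthetic paired-cohort generator with a planted truth record.

Emulates the structure of a large adult male survey extract: ~40 markers in
heterogeneous units, a handful of right-skewed markers, linear age effects on
a subset of markers, latent subgroups, and binary traits whose prevalence is
shifted (on the odds scale) inside chosen subgroups.  Training and validation
cohorts are drawn i.i.d. from the same process so that cross-cohort
reproducibility has a known ground truth.

Generative model per sample ``i`` with subgroup ``k`` and marker ``j``::

    latent  z_ij = centroid[k, j] + age_slope[j] * (age_i - mean_age) + eps,
                   eps ~ Normal(0, marker_noise_sd)
    value   v_ij = scale[j] * g(z_ij) + offset[j]

with ``g = exp`` for skewed markers and identity otherwise.  Traits are
Bernoulli with ``logit p = logit(baseline) + log(odds_ratio)`` when the
(subgroup, trait) pair is planted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortMatrix, TraitTable


class SpecError(ValueError):
    """Raised for invalid generator specifications."""


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _logistic(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


@dataclass
class GeneratorSpec:
    """Full parameterization of the paired-cohort generator."""

    n_train: int = 1200
    n_valid: int = 1200
    n_markers: int = 40
    n_subgroups: int = 5
    mixing_proportions: np.ndarray | None = None  # length K simplex
    centroid_matrix: np.ndarray | None = None  # (K, n_markers) latent means
    marker_noise_sd: float = 1.0
    skewed_markers: tuple[int, ...] = ()
    marker_scales: np.ndarray | None = None
    marker_offsets: np.ndarray | None = None
    age_range: tuple[float, float] = (20.0, 85.0)
    age_slopes: np.ndarray | None = None  # latent units per year
    n_traits: int = 19
    baseline_prevalence: np.ndarray | None = None
    planted_odds: dict[tuple[int, str], float] = field(default_factory=dict)
    missing_rate: float = 0.0
    cohort_shift_sd: float = 0.0  # optional centroid perturbation of the validation cohort
    seed: int = 0

    def __post_init__(self) -> None:
        K, P, T = self.n_subgroups, self.n_markers, self.n_traits
        if min(self.n_train, self.n_valid, P, K, T) <= 0:
            raise SpecError("counts must be positive")
        if K > self.n_train:
            raise SpecError("more subgroups than training samples")
        if self.mixing_proportions is None:
            self.mixing_proportions = np.full(K, 1.0 / K)
        self.mixing_proportions = np.asarray(self.mixing_proportions, float)
        if self.mixing_proportions.shape != (K,):
            raise SpecError("mixing_proportions must have length K")
        if abs(self.mixing_proportions.sum() - 1.0) > 1e-12 or np.any(self.mixing_proportions < 0):
            raise SpecError("mixing proportions must form a simplex (sum 1 within 1e-12)")
        if self.centroid_matrix is None:
            self.centroid_matrix = np.zeros((K, P))
        self.centroid_matrix = np.asarray(self.centroid_matrix, float)
        if self.centroid_matrix.shape != (K, P):
            raise SpecError("centroid_matrix must be K x n_markers")
        if self.marker_noise_sd <= 0:
            raise SpecError("marker_noise_sd must be positive")
        self.skewed_markers = tuple(sorted(int(j) for j in self.skewed_markers))
        if any(j < 0 or j >= P for j in self.skewed_markers):
            raise SpecError("skewed marker index out of range")
        if self.marker_scales is None:
            self.marker_scales = np.ones(P)
        if self.marker_offsets is None:
            self.marker_offsets = np.zeros(P)
        self.marker_scales = np.asarray(self.marker_scales, float)
        self.marker_offsets = np.asarray(self.marker_offsets, float)
        if self.marker_scales.shape != (P,) or self.marker_offsets.shape != (P,):
            raise SpecError("marker scales/offsets must have length n_markers")
        if np.any(self.marker_scales == 0):
            raise SpecError("marker scales must be nonzero")
        lo, hi = self.age_range
        if lo < 20.0:
            raise SpecError("age_range lower bound must be >= 20")
        if hi <= lo:
            raise SpecError("age_range must be increasing")
        if self.age_slopes is None:
            self.age_slopes = np.zeros(P)
        self.age_slopes = np.asarray(self.age_slopes, float)
        if self.age_slopes.shape != (P,):
            raise SpecError("age_slopes must have length n_markers")
        if self.baseline_prevalence is None:
            self.baseline_prevalence = np.full(T, 0.1)
        self.baseline_prevalence = np.asarray(self.baseline_prevalence, float)
        if self.baseline_prevalence.shape != (T,):
            raise SpecError("baseline_prevalence must have length n_traits")
        if np.any((self.baseline_prevalence <= 0) | (self.baseline_prevalence >= 1)):
            raise SpecError("baseline prevalences must lie in (0, 1)")
        for (k, trait), odds in self.planted_odds.items():
            if odds <= 0:
                raise SpecError("odds ratios must be positive")
            if not 1 <= int(k) <= K:
                raise SpecError(f"planted subgroup {k} out of 1..{K}")
            if trait not in self.trait_names:
                raise SpecError(f"planted trait {trait!r} not among generated traits")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing_rate must be in [0, 1)")

    @property
    def trait_names(self) -> list[str]:
        return [f"trait_{t + 1:02d}" for t in range(self.n_traits)]

    @property
    def marker_names(self) -> list[str]:
        return [f"marker_{j + 1:02d}" for j in range(self.n_markers)]

    @property
    def mean_age(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("mixing_proportions", "marker_scales", "marker_offsets",
                    "age_slopes", "baseline_prevalence"):
            d[key] = np.asarray(d[key]).tolist()
        d["centroid_matrix"] = np.asarray(d["centroid_matrix"]).tolist()
        d["skewed_markers"] = list(self.skewed_markers)
        d["age_range"] = list(self.age_range)
        d["planted_odds"] = {f"{k}:{t}": v for (k, t), v in self.planted_odds.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        planted = {}
        for key, v in (d.pop("planted_odds", {}) or {}).items():
            k, trait = key.split(":", 1)
            planted[(int(k), trait)] = float(v)
        for key in ("mixing_proportions", "centroid_matrix", "marker_scales",
                    "marker_offsets", "age_slopes", "baseline_prevalence"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], float)
        if "skewed_markers" in d and d["skewed_markers"] is not None:
            d["skewed_markers"] = tuple(d["skewed_markers"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(planted_odds=planted, **d)


@dataclass
class TruthRecord:
    """Ground truth retained for scoring recovered structure."""

    train_labels: np.ndarray  # 1..K per training sample
    valid_labels: np.ndarray
    planted_pairs: set[tuple[int, str]]
    age_slopes: np.ndarray  # latent-scale slope per marker

    def __post_init__(self) -> None:
        self.train_labels = np.asarray(self.train_labels, int)
        self.valid_labels = np.asarray(self.valid_labels, int)
        if self.train_labels.size and self.train_labels.min() < 1:
            raise SpecError("truth labels must be 1-based")


def separated_spec(
    *,
    n_subgroups: int = 5,
    n_train: int = 1200,
    n_valid: int = 1200,
    n_markers: int = 20,
    n_informative: int = 10,
    separation: float = 4.0,
    noise_sd: float = 1.0,
    n_traits: int = 19,
    planted_odds: dict[tuple[int, str], float] | None = None,
    baseline_prevalence: float = 0.1,
    skewed_markers: tuple[int, ...] = (),
    marker_scales: np.ndarray | None = None,
    marker_offsets: np.ndarray | None = None,
    age_slopes: np.ndarray | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    **extra,
) -> GeneratorSpec:
    """Build a spec whose subgroup centroids are guaranteed pairwise separated
    by at least ``separation * noise_sd`` (Euclidean, over the informative
    markers).

    Centroids are ``+/- (separation / 2) * noise_sd`` sign patterns on the
    informative markers, so two subgroups differing on ``h`` markers sit
    ``separation * sqrt(h) * noise_sd`` apart (a per-marker mean gap of
    ``separation * noise_sd`` on every differing marker).  Patterns are
    redrawn until every pair differs on at least ``max(2, n_informative//3)``
    markers, which keeps the centroids angularly separated as well (needed
    by correlation-based similarity).  Deterministic given ``seed``.
    """
    if n_informative > n_markers:
        raise SpecError("n_informative exceeds n_markers")
    if n_subgroups > 2 ** n_informative:
        raise SpecError("too few informative markers for distinct sign patterns")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0F0)))
    floor = separation * noise_sd
    amplitude = separation / 2.0 * noise_sd
    h_min = max(2, n_informative // 3)
    for _ in range(1000):
        signs = rng.choice([-1.0, 1.0], size=(n_subgroups, n_informative))
        C = signs * amplitude
        d = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        ham = (signs[:, None, :] != signs[None, :, :]).sum(-1)
        np.fill_diagonal(d, np.inf)
        np.fill_diagonal(ham, n_informative)
        if d.min() >= floor and ham.min() >= h_min:
            break
    else:  # pragma: no cover - patterns separate quickly in practice
        raise SpecError("could not construct separated centroids")
    centroids = np.zeros((n_subgroups, n_markers))
    centroids[:, :n_informative] = C
    return GeneratorSpec(
        n_train=n_train,
        n_valid=n_valid,
        n_markers=n_markers,
        n_subgroups=n_subgroups,
        centroid_matrix=centroids,
        marker_noise_sd=noise_sd,
        skewed_markers=skewed_markers,
        marker_scales=marker_scales,
        marker_offsets=marker_offsets,
        age_slopes=age_slopes,
        n_traits=n_traits,
        baseline_prevalence=np.full(n_traits, baseline_prevalence),
        planted_odds=dict(planted_odds or {}),
        missing_rate=missing_rate,
        seed=seed,
        **extra,
    )


def default_spec(seed: int = 0) -> GeneratorSpec:
    """NHANES-like default: 40 mixed-unit markers (8 right-skewed), 5 latent
    subgroups separated on 10 markers, linear age effects on 6 markers, and
    19 traits of which 5 are planted (one per subgroup, OR 6)."""
    n_markers = 40
    # informative markers carry modest units; the large-unit markers are
    # uninformative, so unscaled pipelines are dominated by unit noise
    scales = np.array([[0.4, 1.0, 3.0][j % 3] if j < 10
                       else [12.0, 85.0, 140.0][j % 3] for j in range(n_markers)])
    offsets = np.array([[0.0, 40.0, 5.0, 110.0, 1.5][j % 5] for j in range(n_markers)])
    offsets[32:] = 0.0  # skewed markers stay pure-scale so a log restores normality
    slopes = np.zeros(n_markers)
    slopes[[10, 11, 12, 13, 14, 15]] = 0.02  # ~0.38 latent sd across the age span
    planted = {(k, f"trait_{k:02d}"): 6.0 for k in range(1, 6)}
    return separated_spec(
        n_subgroups=5,
        n_train=1200,
        n_valid=1200,
        n_markers=n_markers,
        n_informative=10,
        separation=4.0,
        noise_sd=1.0,
        n_traits=19,
        planted_odds=planted,
        baseline_prevalence=0.1,
        skewed_markers=tuple(range(32, 40)),
        marker_scales=scales,
        marker_offsets=offsets,
        age_slopes=slopes,
        seed=seed,
    )


def _draw_cohort(
    spec: GeneratorSpec,
    n: int,
    seed_seq: np.random.SeedSequence,
    id_prefix: str,
    centroids: np.ndarray,
) -> tuple[CohortMatrix, TraitTable, np.ndarray]:
    rng = np.random.default_rng(seed_seq)
    K, P, T = spec.n_subgroups, spec.n_markers, spec.n_traits
    groups = rng.choice(K, size=n, p=spec.mixing_proportions) + 1
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    latent = (
        centroids[groups - 1]
        + np.outer(ages - spec.mean_age, spec.age_slopes)
        + rng.normal(0.0, spec.marker_noise_sd, size=(n, P))
    )
    observed = latent.copy()
    if spec.skewed_markers:
        idx = list(spec.skewed_markers)
        observed[:, idx] = np.exp(latent[:, idx])
    observed = observed * spec.marker_scales + spec.marker_offsets

    probs = np.tile(spec.baseline_prevalence, (n, 1))
    for (k, trait), odds in sorted(spec.planted_odds.items()):
        t = spec.trait_names.index(trait)
        in_k = groups == k
        probs[in_k, t] = _logistic(_logit(spec.baseline_prevalence[t]) + np.log(odds))
    traits = (rng.uniform(size=(n, T)) < probs).astype(float)

    mask = np.zeros((n, P), dtype=bool)
    if spec.missing_rate > 0:
        mask = rng.uniform(size=(n, P)) < spec.missing_rate

    ids = np.array([f"{id_prefix}{i + 1:05d}" for i in range(n)])
    cohort = CohortMatrix(ids, ages, observed, spec.marker_names, missing_mask=mask)
    table = TraitTable(ids, spec.trait_names, traits)
    return cohort, table, groups


def generate_cohort_pair(
    spec: GeneratorSpec,
) -> tuple[CohortMatrix, TraitTable, CohortMatrix, TraitTable, TruthRecord]:
    """Draw training and validation cohorts i.i.d. from ``spec``.

    Returns ``(train_cohort, train_traits, valid_cohort, valid_traits,
    truth)``.  Identical spec + seed yields bit-identical output.
    """
    ss = np.random.SeedSequence(int(spec.seed))
    ss_train, ss_valid, ss_shift = ss.spawn(3)
    valid_centroids = spec.centroid_matrix
    if spec.cohort_shift_sd > 0:
        shift_rng = np.random.default_rng(ss_shift)
        valid_centroids = spec.centroid_matrix + shift_rng.normal(
            0.0, spec.cohort_shift_sd, size=spec.centroid_matrix.shape
        )
    train, train_traits, g_train = _draw_cohort(spec, spec.n_train, ss_train, "TR", spec.centroid_matrix)
    valid, valid_traits, g_valid = _draw_cohort(spec, spec.n_valid, ss_valid, "VA", valid_centroids)
    truth = TruthRecord(
        train_labels=g_train,
        valid_labels=g_valid,
        planted_pairs=set(spec.planted_odds.keys()),
        age_slopes=spec.age_slopes.copy(),
    )
    return train, train_traits, valid, valid_traits, truth
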