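"""Pre-processing variants: raw, normal transform, Z-score, age-adjusted Z-score.

The normal transform replaces right/left-skewed markers (|sample skewness|
above 1) by their natural log.  Age adjustment removes the least-squares
linear age component from markers that pass a correlation gate (two-sided
p < 0.05 and |r| > 0.1) and recenters at the original marker mean:

    V' = V - (a * age + b) + m

so gated markers end up exactly uncorrelated with age on the fitting sample
while keeping their mean.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortError, CohortMatrix

log = logging.getLogger(__name__)

SKEW_GATE = 1.0
AGE_P_GATE = 0.05
AGE_R_GATE = 0.1


class PipelineVariant(str, enum.Enum):
    """The four pre-processing arms of the experiment grid."""

    RAW = "raw"
    NORM_TRANSFORM = "norm_transform"
    ZSCORE = "zscore"
    AGE_ADJUST_ZSCORE = "age_adjust_zscore"


class DegenerateMarkerError(CohortError):
    pass


def sample_skewness(values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson standardized third moment,
    ``g1 * sqrt(n(n-1)) / (n-2)``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise DegenerateMarkerError("skewness needs at least 3 values")
    if np.std(values, ddof=1) == 0:
        raise DegenerateMarkerError("degenerate marker: zero variance")
    return float(stats.skew(values, bias=False))


def _analysis_values(cohort: CohortMatrix) -> np.ndarray:
    if cohort.has_missing():
        raise CohortError(
            "cohort still has missing values; apply complete_cases/impute_median first"
        )
    return cohort.markers


def complete_cases(cohort: CohortMatrix) -> tuple[CohortMatrix, np.ndarray]:
    """Drop samples with any missing marker; returns (cohort, dropped ids)."""
    keep = ~cohort.missing_mask.any(axis=1)
    dropped = cohort.sample_ids[~keep]
    if dropped.size:
        log.info("complete-case filter dropped %d/%d samples", dropped.size, cohort.n_samples)
    out = cohort.take(np.flatnonzero(keep))
    out.missing_mask[:] = False
    return out, dropped


def impute_median(cohort: CohortMatrix) -> CohortMatrix:
    """Replace missing cells by the per-marker median of observed values."""
    values = cohort.markers.copy()
    for j in range(cohort.n_markers):
        miss = cohort.missing_mask[:, j]
        if miss.any():
            obs = values[~miss, j]
            if obs.size == 0:
                raise DegenerateMarkerError(f"marker {cohort.marker_names[j]} fully missing")
            values[miss, j] = np.median(obs)
    out = cohort.copy(markers=values)
    out.missing_mask[:] = False
    return out


def normal_transform(cohort: CohortMatrix) -> tuple[CohortMatrix, set[str]]:
    """Natural-log transform every marker whose |skewness| exceeds the gate."""
    X = _analysis_values(cohort).copy()
    transformed: set[str] = set()
    for j, name in enumerate(cohort.marker_names):
        if abs(sample_skewness(X[:, j])) > SKEW_GATE:
            if np.any(X[:, j] <= 0):
                raise CohortError(
                    f"marker {name!r} selected for log transform has non-positive values"
                )
            X[:, j] = np.log(X[:, j])
            transformed.add(name)
    return cohort.copy(markers=X), transformed


def zscore_normalize(
    cohort: CohortMatrix,
    params: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CohortMatrix, tuple[np.ndarray, np.ndarray]]:
    """Standardize each marker to mean 0, sample sd 1 (ddof=1).

    Pass previously fitted ``(means, sds)`` to re-apply a frozen transform.
    """
    X = _analysis_values(cohort)
    if params is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sds == 0)
        if bad.size:
            names = [cohort.marker_names[j] for j in bad[:5]]
            raise DegenerateMarkerError(f"zero-variance markers: {names}")
    else:
        means, sds = params
    Z = (X - means) / sds
    return cohort.copy(markers=Z), (means, sds)


@dataclass
class AgeAdjustModel:
    """Fitted per-marker linear age correction with the gating statistics."""

    marker_names: list[str]
    gated: np.ndarray  # bool per marker
    slope: np.ndarray  # a, marker units / year
    intercept: np.ndarray  # b
    recenter: np.ndarray  # m, pre-adjustment marker mean
    pearson_r: np.ndarray
    pearson_p: np.ndarray

    def as_table(self) -> list[dict]:
        return [
            {
                "marker": self.marker_names[j],
                "gated": bool(self.gated[j]),
                "slope": float(self.slope[j]),
                "intercept": float(self.intercept[j]),
                "recenter": float(self.recenter[j]),
                "r": float(self.pearson_r[j]),
                "p": float(self.pearson_p[j]),
            }
            for j in range(len(self.marker_names))
        ]


def age_adjust(
    cohort: CohortMatrix,
    model: AgeAdjustModel | None = None,
) -> tuple[CohortMatrix, AgeAdjustModel]:
    """Remove the linear age component from markers passing the gate.

    Gate: two-sided Pearson p < 0.05 and |r| > 0.1.  Pass a fitted ``model``
    to re-apply training-fitted parameters to another cohort.
    """
    X = _analysis_values(cohort)
    ages = cohort.ages
    if np.std(ages) == 0:
        raise CohortError("constant age vector: age adjustment undefined")
    if model is None:
        P = cohort.n_markers
        gated = np.zeros(P, dtype=bool)
        slope = np.zeros(P)
        intercept = np.zeros(P)
        recenter = X.mean(axis=0)
        rs = np.zeros(P)
        ps = np.ones(P)
        for j in range(P):
            if np.std(X[:, j]) == 0:  # constant marker can't correlate with age
                continue
            r, p = stats.pearsonr(X[:, j], ages)
            rs[j], ps[j] = r, p
            if p < AGE_P_GATE and abs(r) > AGE_R_GATE:
                a, b = np.polyfit(ages, X[:, j], 1)
                gated[j] = True
                slope[j], intercept[j] = a, b
        model = AgeAdjustModel(list(cohort.marker_names), gated, slope, intercept,
                               recenter, rs, ps)
    out = X.copy()
    g = model.gated
    out[:, g] = (
        X[:, g]
        - (np.outer(ages, model.slope[g]) + model.intercept[g])
        + model.recenter[g]
    )
    return cohort.copy(markers=out), model


@dataclass
class PreprocessRecord:
    """Provenance of one pre-processing run (enough to reproduce it)."""

    variant: PipelineVariant
    dropped_ids: list[str] = field(default_factory=list)
    log_transformed: set[str] = field(default_factory=set)
    zscore_params: tuple[np.ndarray, np.ndarray] | None = None
    age_model: AgeAdjustModel | None = None


def preprocess(
    cohort: CohortMatrix,
    variant: PipelineVariant | str,
    *,
    aggregate_transforms: bool = False,
    missing: str = "complete",
    frozen: PreprocessRecord | None = None,
) -> tuple[CohortMatrix, PreprocessRecord]:
    """Apply one pre-processing variant.

    ``raw`` is the identity; ``norm_transform`` applies the skewness-gated
    log only; ``zscore`` standardizes; ``age_adjust_zscore`` age-adjusts then
    standardizes.  With ``aggregate_transforms=True`` the variants chain
    (log -> [age adjust] -> Z-score) instead of being applied in isolation.
    ``frozen`` re-applies transforms fitted on another cohort.
    """
    variant = PipelineVariant(variant)
    rec = PreprocessRecord(variant=variant)
    if cohort.has_missing():
        if missing == "complete":
            cohort, dropped = complete_cases(cohort)
            rec.dropped_ids = [str(s) for s in dropped]
        elif missing == "impute":
            cohort = impute_median(cohort)
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    if variant is PipelineVariant.RAW:
        return cohort.copy(), rec

    out = cohort
    wants_log = variant is PipelineVariant.NORM_TRANSFORM or aggregate_transforms
    if wants_log:
        out, rec.log_transformed = normal_transform(out)
    if variant is PipelineVariant.NORM_TRANSFORM:
        return out, rec
    if variant is PipelineVariant.AGE_ADJUST_ZSCORE:
        out, rec.age_model = age_adjust(
            out, model=frozen.age_model if frozen is not None else None
        )
    out, rec.zscore_params = zscore_normalize(
        out, params=frozen.zscore_params if frozen is not None else None
    )
    return out, rec
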