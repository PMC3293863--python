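"""Core data containers shared by every stage of the pipeline.

A cohort is a samples x markers numeric matrix with per-sample ages, an
optional missing mask, plus a parallel table of binary health/lifestyle
traits.  A clustering is a total assignment of sample ids to dense labels
``1..K`` with ``UNCLASSIFIED`` (0) reserved for samples a graph clustering
declined to place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

#: label reserved for samples left out of every cluster
UNCLASSIFIED = 0

MIN_AGE_YEARS = 20.0


class CohortError(ValueError):
    """Raised for structurally invalid cohort inputs."""


@dataclass
class CohortMatrix:
    """Samples x markers matrix with ids, ages and a missing mask.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, length ``n``.
    ages
        Age in years per sample; every age must be >= 20 (the cohorts this
        pipeline targets are restricted to adults).
    markers
        ``(n, p)`` float matrix of marker values on their observed scales.
    marker_names
        ``p`` unique marker names.
    missing_mask
        ``(n, p)`` boolean mask, ``True`` where the value is missing.  NaNs
        in ``markers`` are folded into the mask automatically.
    """

    sample_ids: np.ndarray
    ages: np.ndarray
    markers: np.ndarray
    marker_names: list[str]
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.ages = np.asarray(self.ages, dtype=float)
        self.markers = np.asarray(self.markers, dtype=float)
        self.marker_names = list(self.marker_names)
        n, p = self.markers.shape if self.markers.ndim == 2 else (len(self.markers), -1)
        if self.markers.ndim != 2:
            raise CohortError("markers must be a 2-D matrix")
        if len(self.sample_ids) != n or len(self.ages) != n:
            raise CohortError("sample_ids/ages length does not match marker rows")
        if len(self.marker_names) != p:
            raise CohortError("marker_names length does not match marker columns")
        if len(set(map(str, self.sample_ids))) != n:
            raise CohortError("sample ids must be unique")
        if len(set(self.marker_names)) != p:
            raise CohortError("marker names must be unique")
        if np.any(~np.isfinite(self.ages)):
            raise CohortError("ages contain non-finite values")
        if np.any(self.ages < MIN_AGE_YEARS):
            raise CohortError(f"ages below {MIN_AGE_YEARS} are not supported")
        if np.any(np.isinf(self.markers)):
            raise CohortError("markers contain infinities")
        nanmask = np.isnan(self.markers)
        if self.missing_mask is None:
            self.missing_mask = nanmask
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool) | nanmask
        if self.missing_mask.shape != self.markers.shape:
            raise CohortError("missing_mask shape does not match markers")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.markers.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def copy(self, markers: np.ndarray | None = None) -> "CohortMatrix":
        return CohortMatrix(
            sample_ids=self.sample_ids.copy(),
            ages=self.ages.copy(),
            markers=self.markers.copy() if markers is None else np.asarray(markers, float),
            marker_names=list(self.marker_names),
            missing_mask=self.missing_mask.copy(),
        )

    def take(self, idx: np.ndarray) -> "CohortMatrix":
        """Row subset (positional indices), preserving order of ``idx``."""
        idx = np.asarray(idx)
        return CohortMatrix(
            sample_ids=self.sample_ids[idx],
            ages=self.ages[idx],
            markers=self.markers[idx],
            marker_names=list(self.marker_names),
            missing_mask=self.missing_mask[idx],
        )

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        values = self.markers.copy()
        values[self.missing_mask] = np.nan
        df = pd.DataFrame(values, columns=self.marker_names)
        df.insert(0, "age_years", self.ages)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortMatrix":
        if "sample_id" not in df.columns or "age_years" not in df.columns:
            raise CohortError("cohort table needs 'sample_id' and 'age_years' columns")
        marker_names = [c for c in df.columns if c not in ("sample_id", "age_years")]
        markers = df[marker_names].to_numpy(dtype=float)
        return cls(
            sample_ids=df["sample_id"].astype(str).to_numpy(),
            ages=df["age_years"].to_numpy(dtype=float),
            markers=markers,
            marker_names=marker_names,
        )

    @classmethod
    def from_csv(cls, path) -> "CohortMatrix":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class TraitTable:
    """Samples x binary traits with explicit unknown status (NaN)."""

    sample_ids: np.ndarray
    trait_names: list[str]
    values: np.ndarray  # (n, t) float: 0.0, 1.0 or NaN for unknown

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.trait_names = list(self.trait_names)
        if self.values.ndim != 2:
            raise CohortError("trait values must be 2-D")
        if self.values.shape[0] != len(self.sample_ids):
            raise CohortError("trait rows do not match sample ids")
        if self.values.shape[1] != len(self.trait_names):
            raise CohortError("trait columns do not match trait names")
        known = self.values[~np.isnan(self.values)]
        if known.size and not np.all(np.isin(known, (0.0, 1.0))):
            raise CohortError("trait values must be 0, 1 or NA")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(trait)]

    def subset(self, idx: np.ndarray) -> "TraitTable":
        idx = np.asarray(idx)
        return TraitTable(self.sample_ids[idx], list(self.trait_names), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitTable":
        if "sample_id" not in df.columns:
            raise CohortError("trait table needs a 'sample_id' column")
        traits = [c for c in df.columns if c != "sample_id"]
        return cls(
            sample_ids=df["sample_id"].astype(str).to_numpy(),
            trait_names=traits,
            values=df[traits].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class Clustering:
    """Total assignment of sample ids to labels ``1..K`` or ``UNCLASSIFIED``."""

    sample_ids: np.ndarray
    labels: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(self.labels):
            raise CohortError("labels length does not match sample ids")
        if np.any(self.labels < 0):
            raise CohortError("labels must be >= 0 (0 = UNCLASSIFIED)")

    @property
    def cluster_labels(self) -> list[int]:
        """Sorted distinct cluster labels in use (UNCLASSIFIED excluded).

        Clustering algorithms emit dense ``1..K``; a projection may leave a
        training label empty, so gaps are tolerated here.
        """
        used = np.unique(self.labels[self.labels != UNCLASSIFIED])
        return [int(u) for u in used]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    @property
    def n_unclassified(self) -> int:
        return int(np.sum(self.labels == UNCLASSIFIED))

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def sizes(self) -> dict[int, int]:
        return {k: int(np.sum(self.labels == k)) for k in self.cluster_labels}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Clustering":
        df = pd.read_csv(path)
        return cls(df["sample_id"].astype(str).to_numpy(), df["cluster"].to_numpy(int))


def compact_labels(raw: Sequence[int], unclassified_value: int = -1) -> np.ndarray:
    """Map arbitrary integer labels onto dense ``1..K``; order of first
    appearance (by ascending sample index) fixes the numbering so the result
    is deterministic."""
    raw = np.asarray(raw)
    out = np.zeros(len(raw), dtype=int)
    mapping: dict[int, int] = {}
    nxt = 1
    for i, lab in enumerate(raw):
        if lab == unclassified_value:
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def pearson_rows(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between the rows of ``X``.

    Requires >= 3 columns and non-constant rows (correlation of a constant
    profile is undefined).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise CohortError("pairwise correlation needs at least 3 markers")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise CohortError(f"constant marker profile for sample rows {bad[:5].tolist()}")
    U = Xc / norms[:, None]
    return np.clip(U @ U.T, -1.0, 1.0)


def pearson_vec(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise CohortError("correlation of a constant vector is undefined")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))
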