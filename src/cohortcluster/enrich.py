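"""Hypergeometric trait enrichment per cluster and cross-cohort validation.

For each (cluster, trait) pair the over-representation of trait-positive
samples inside the cluster is scored with an exact hypergeometric upper-tail
probability over the tested population (clustered samples whose trait status
is known).  The enrichment factor is the trait frequency in the cluster
divided by its frequency in the population.  A *validated* enrichment is a
(cluster, trait) pair significant in both the training clustering and the
projected validation clustering; the cross-cohort bookkeeping mirrors a
valid/total accounting per pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import UNCLASSIFIED, Clustering, CohortError, TraitTable

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_POSITIVES = 30


def hypergeom_pvalue(N: int, K_trait: int, n_cluster: int, k_in: int) -> float:
    """Upper-tail ``P(X >= k_in)`` for ``X ~ Hypergeom(N, K_trait, n_cluster)``.

    Computed by summing exact pmf terms from ``k_in`` to ``min(K_trait,
    n_cluster)``.
    """
    N, K_trait, n_cluster, k_in = int(N), int(K_trait), int(n_cluster), int(k_in)
    if not (0 <= K_trait <= N and 0 <= n_cluster <= N):
        raise CohortError("inconsistent hypergeometric counts")
    hi = min(K_trait, n_cluster)
    if not 0 <= k_in <= hi:
        raise CohortError(f"k_in={k_in} outside 0..{hi}")
    ks = np.arange(k_in, hi + 1)
    p = float(stats.hypergeom.pmf(ks, N, K_trait, n_cluster).sum())
    return min(p, 1.0)


@dataclass
class EnrichmentRecord:
    """One (cluster, trait) over-representation test."""

    cluster: int
    trait: str
    N: int  # tested population size (known-status clustered samples)
    K_trait: int  # trait positives in the population
    n_cluster: int  # cluster members with known status
    k_in: int  # trait positives inside the cluster
    p: float
    factor: float
    significant: bool

    @property
    def key(self) -> tuple[int, str]:
        return (self.cluster, self.trait)


def enrich_clusters(
    clustering: Clustering,
    traits: TraitTable,
    *,
    alpha: float = DEFAULT_ALPHA,
    min_positives: int = DEFAULT_MIN_POSITIVES,
    bh_correct: bool = False,
) -> list[EnrichmentRecord]:
    """Test every (cluster, trait) pair; traits with fewer than
    ``min_positives`` positives in the tested population are skipped.

    Population per trait: clustered samples whose trait status is known.
    With ``bh_correct=True`` the significance flag uses Benjamini-Hochberg
    adjusted p-values (raw p is always reported).
    """
    id_to_row = {str(s): i for i, s in enumerate(traits.sample_ids)}
    rows = []
    cl_rows = []
    for i, sid in enumerate(clustering.sample_ids):
        j = id_to_row.get(str(sid))
        if j is not None and clustering.labels[i] != UNCLASSIFIED:
            rows.append(j)
            cl_rows.append(i)
    if not rows:
        raise CohortError("clustering and trait table share no classified sample ids")
    tvals = traits.values[np.asarray(rows)]
    labels = clustering.labels[np.asarray(cl_rows)]

    records: list[EnrichmentRecord] = []
    for t, trait in enumerate(traits.trait_names):
        col = tvals[:, t]
        known = ~np.isnan(col)
        N = int(known.sum())
        K_trait = int(np.nansum(col))
        if K_trait < min_positives:
            continue
        base = K_trait / N
        for lab in clustering.cluster_labels:
            in_cl = (labels == lab) & known
            n_cluster = int(in_cl.sum())
            if n_cluster == 0:
                continue
            k_in = int(col[in_cl].sum())
            p = hypergeom_pvalue(N, K_trait, n_cluster, k_in)
            factor = (k_in / n_cluster) / base
            records.append(
                EnrichmentRecord(int(lab), trait, N, K_trait, n_cluster, k_in,
                                 p, factor, significant=p < alpha)
            )
    if bh_correct and records:
        ps = np.array([r.p for r in records])
        m = ps.size
        order = np.argsort(ps, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, ps[idx] * m / (rank + 1))
            adj[idx] = running
        for r, q in zip(records, adj):
            r.significant = q < alpha
    return records


@dataclass
class ValidationReport:
    """Cross-cohort accounting for one preprocessing x algorithm pipeline."""

    total_train_enrichments: int
    valid_enrichments: int
    distinct_train_traits: int
    distinct_valid_traits: int
    enriched_clusters: int
    validated_clusters: int
    pipeline_factor: float
    valid_pairs: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.valid_enrichments <= self.total_train_enrichments
        assert self.validated_clusters <= self.enriched_clusters
        assert self.distinct_valid_traits <= self.distinct_train_traits

    @property
    def valid_ratio(self) -> str:
        return f"{self.valid_enrichments}/{self.total_train_enrichments}"

    @property
    def distinct_ratio(self) -> str:
        return f"{self.distinct_valid_traits}/{self.distinct_train_traits}"

    @property
    def cluster_ratio(self) -> str:
        return f"{self.validated_clusters}/{self.enriched_clusters}"


def validate_enrichments(
    train_records: list[EnrichmentRecord],
    valid_records: list[EnrichmentRecord],
) -> ValidationReport:
    """Cross-reference significant enrichments between cohorts.

    A valid enrichment is a (cluster, trait) pair significant in both record
    lists (cluster labels are shared via projection).  The pipeline
    enrichment factor averages the validation-cohort factors of the three
    smallest-p valid enrichments (ordered by validation p).
    """
    sig_train = {r.key: r for r in train_records if r.significant}
    sig_valid = {r.key: r for r in valid_records if r.significant}
    valid_keys = sorted(set(sig_train) & set(sig_valid))

    train_clusters = {c for c, _ in sig_train}
    valid_clusters_set = {c for c, _ in valid_keys}
    top3 = sorted(valid_keys, key=lambda k: (sig_valid[k].p, k))[:3]
    factor = float(np.mean([sig_valid[k].factor for k in top3])) if top3 else float("nan")
    return ValidationReport(
        total_train_enrichments=len(sig_train),
        valid_enrichments=len(valid_keys),
        distinct_train_traits=len({t for _, t in sig_train}),
        distinct_valid_traits=len({t for _, t in valid_keys}),
        enriched_clusters=len(train_clusters),
        validated_clusters=len(valid_clusters_set),
        pipeline_factor=factor,
        valid_pairs=list(valid_keys),
    )
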