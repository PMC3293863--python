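"""Experiment grid driver: variants x algorithms, end to end.

For every requested preprocessing variant and clustering algorithm the
driver preprocesses both cohorts (refit per cohort by default), clusters the
training cohort, scores cluster quality under dropout resampling, trains a
projector and projects the validation cohort, runs trait enrichment on both
cohorts and cross-validates the enrichments.  The cluster count for
K-means/SOM is taken from the full-data CLICK run of the same variant, or
from the config when CLICK is not in the algorithm list.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import ClickParams, click_cluster, run_algorithm
from .cohort import Clustering, CohortError, CohortMatrix, TraitTable
from .enrich import EnrichmentRecord, ValidationReport, enrich_clusters, validate_enrichments
from .preprocess import PipelineVariant, preprocess
from .project import ProjectorConfig, project, train_projector
from .quality import QualitySummary, cluster_quality, quality_resample
from .synth import GeneratorSpec, default_spec, generate_cohort_pair

log = logging.getLogger(__name__)

ALL_VARIANTS = [v.value for v in PipelineVariant]
ALL_ALGORITHMS = ["click", "kmeans", "som"]


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment run."""

    mode: str = "synthetic"  # "synthetic" or "files"
    generator: GeneratorSpec | None = None
    train_cohort: str | None = None
    train_traits: str | None = None
    valid_cohort: str | None = None
    valid_traits: str | None = None
    variants: list[str] = field(default_factory=lambda: list(ALL_VARIANTS))
    algorithms: list[str] = field(default_factory=lambda: list(ALL_ALGORITHMS))
    aggregate_transforms: bool = False
    freeze_preprocess: bool = False
    missing: str = "complete"
    resample_frac: float = 0.03
    resample_reps: int = 10
    click_params: dict = field(default_factory=dict)
    kmeans_k: int | None = None
    som_cells: int | None = None
    enrichment_alpha: float = 0.05
    enrichment_min_positives: int = 30
    enrichment_bh: bool = False
    run_enrichment: bool = True
    projector_method: str = "mlp"
    projector_hidden_multiplier: int = 2
    projector_max_iter: int = 300
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise CohortError(f"unknown mode {self.mode!r}")
        if not self.variants or not self.algorithms:
            raise CohortError("need at least one variant and one algorithm")
        for v in self.variants:
            PipelineVariant(v)
        for a in self.algorithms:
            if a not in ALL_ALGORITHMS:
                raise CohortError(f"unknown algorithm {a!r}")
        if self.mode == "files":
            if not self.train_cohort or not self.valid_cohort:
                raise CohortError("files mode needs train_cohort and valid_cohort paths")
            if self.run_enrichment and (not self.train_traits or not self.valid_traits):
                raise CohortError("enrichment requested but trait tables are missing")
        if "click" not in self.algorithms:
            if "kmeans" in self.algorithms and self.kmeans_k is None:
                raise CohortError("kmeans without click needs kmeans_k in config")
            if "som" in self.algorithms and self.som_cells is None:
                raise CohortError("som without click needs som_cells in config")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        cfg = cls(**d)
        if gen is not None:
            cfg.generator = GeneratorSpec.from_dict(gen)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def dump_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ComboResult:
    variant: str
    algorithm: str
    train_clustering: Clustering
    train_quality: QualitySummary
    valid_clustering: Clustering | None
    valid_quality: tuple[float, float, float] | None
    train_records: list[EnrichmentRecord]
    valid_records: list[EnrichmentRecord]
    report: ValidationReport | None


def _combo_seed(seed: int, vi: int, ai: int, purpose: int) -> int:
    ss = np.random.SeedSequence((int(seed), vi, ai, purpose))
    return int(ss.generate_state(1)[0])


def _load_inputs(config: ExperimentConfig):
    if config.mode == "synthetic":
        spec = config.generator or default_spec(seed=config.seed)
        train, train_tr, valid, valid_tr, _truth = generate_cohort_pair(spec)
        return train, train_tr, valid, valid_tr
    train = CohortMatrix.from_csv(config.train_cohort)
    valid = CohortMatrix.from_csv(config.valid_cohort)
    train_tr = TraitTable.from_csv(config.train_traits) if config.train_traits else None
    valid_tr = TraitTable.from_csv(config.valid_traits) if config.valid_traits else None
    return train, train_tr, valid, valid_tr


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> dict:
    """Run the full grid and write the report bundle; returns it in memory."""
    config.validate()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump_yaml(out / "resolved_config.yaml")

    train, train_traits, valid, valid_traits = _load_inputs(config)
    do_enrich = config.run_enrichment and train_traits is not None and valid_traits is not None

    click_params = ClickParams(**config.click_params) if config.click_params else ClickParams()
    results: list[ComboResult] = []
    log_lines: list[str] = [f"seed={config.seed}", f"mode={config.mode}",
                            f"n_train={train.n_samples}", f"n_valid={valid.n_samples}"]

    for vi, variant in enumerate(config.variants):
        pre_train, rec_train = preprocess(
            train, variant, aggregate_transforms=config.aggregate_transforms,
            missing=config.missing)
        frozen = rec_train if config.freeze_preprocess else None
        pre_valid, rec_valid = preprocess(
            valid, variant, aggregate_transforms=config.aggregate_transforms,
            missing=config.missing, frozen=frozen)
        if rec_train.dropped_ids or rec_valid.dropped_ids:
            log_lines.append(
                f"variant={variant} dropped_train={len(rec_train.dropped_ids)} "
                f"dropped_valid={len(rec_valid.dropped_ids)}")

        click_k: int | None = None
        if "click" in config.algorithms:
            click_full = click_cluster(pre_train, click_params)
            click_k = max(click_full.n_clusters, 1)
            log_lines.append(f"variant={variant} click_K={click_k}")

        for ai, algorithm in enumerate(config.algorithms):
            seed_c = _combo_seed(config.seed, vi, ai, 1)
            k = click_k if click_k is not None else (
                config.kmeans_k if algorithm == "kmeans" else config.som_cells)
            summary = quality_resample(
                train, variant, algorithm,
                frac=config.resample_frac, n_reps=config.resample_reps,
                seed=seed_c, k=k, click_params=click_params,
                aggregate_transforms=config.aggregate_transforms,
                missing=config.missing)
            train_cl = run_algorithm(pre_train, algorithm, k=k,
                                     click_params=click_params, seed=seed_c)

            proj_cfg = ProjectorConfig(
                method=config.projector_method,
                hidden_multiplier=config.projector_hidden_multiplier,
                max_iter=config.projector_max_iter,
                seed=_combo_seed(config.seed, vi, ai, 2))
            projector = train_projector(pre_train, train_cl, proj_cfg)
            valid_cl = project(projector, pre_valid)
            vq = cluster_quality(pre_valid, valid_cl)

            train_records: list[EnrichmentRecord] = []
            valid_records: list[EnrichmentRecord] = []
            report: ValidationReport | None = None
            if do_enrich:
                kwargs = dict(alpha=config.enrichment_alpha,
                              min_positives=config.enrichment_min_positives,
                              bh_correct=config.enrichment_bh)
                train_records = enrich_clusters(train_cl, train_traits, **kwargs)
                valid_records = enrich_clusters(valid_cl, valid_traits, **kwargs)
                report = validate_enrichments(train_records, valid_records)

            results.append(ComboResult(variant, algorithm, train_cl, summary,
                                       valid_cl, vq, train_records, valid_records, report))
            log_lines.append(
                f"combo variant={variant} algorithm={algorithm} seed={seed_c} "
                f"K={train_cl.n_clusters} unclassified={train_cl.n_unclassified} "
                f"diff={summary.diff:.4f} proj_acc={projector.train_accuracy:.3f}")

    bundle = _render_bundle(results, do_enrich)
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    bundle["_results"] = results
    return bundle


def _pipeline_name(r: ComboResult) -> str:
    return f"{r.variant}+{r.algorithm}"


def _render_bundle(results: list[ComboResult], do_enrich: bool) -> dict[str, pd.DataFrame]:
    quality_rows = []
    for r in results:
        s = r.train_quality
        row = {
            "variant": r.variant,
            "algorithm": r.algorithm,
            "train_K": s.K,
            "train_K_mean": round(s.mean_K, 6),
            "train_K_sd": round(s.sd_K, 6),
            "train_diff": round(s.diff, 6),
            "train_diff_mean": round(s.mean_diff, 6),
            "train_diff_sd": round(s.sd_diff, 6),
        }
        if r.valid_quality is not None:
            row["valid_K"] = r.valid_clustering.n_clusters
            row["valid_diff"] = round(r.valid_quality[2], 6)
        quality_rows.append(row)
    bundle = {"quality_table": pd.DataFrame(quality_rows)}

    if do_enrich:
        val_rows = []
        grid: dict[str, dict[str, str]] = {}
        rec_rows = []
        for r in results:
            rep = r.report
            val_rows.append({
                "variant": r.variant,
                "algorithm": r.algorithm,
                "valid_enrichments": rep.valid_ratio,
                "distinct": rep.distinct_ratio,
                "validated_clusters": rep.cluster_ratio,
                "enrichment_factor": round(rep.pipeline_factor, 3)
                if np.isfinite(rep.pipeline_factor) else "",
            })
            for _, trait in rep.valid_pairs:
                grid.setdefault(trait, {})[_pipeline_name(r)] = "Y"
            for cohort, records in (("train", r.train_records), ("valid", r.valid_records)):
                for rec in records:
                    rec_rows.append({
                        "pipeline": _pipeline_name(r), "cohort": cohort,
                        "cluster": rec.cluster, "trait": rec.trait,
                        "population": rec.N, "trait_positives": rec.K_trait,
                        "cluster_size": rec.n_cluster, "positives_in_cluster": rec.k_in,
                        "p_value": rec.p, "enrichment_factor": round(rec.factor, 6),
                        "significant": rec.significant,
                    })
        bundle["validation_table"] = pd.DataFrame(val_rows)
        pipelines = [_pipeline_name(r) for r in results]
        grid_rows = [
            {"trait": trait, **{p: grid[trait].get(p, "") for p in pipelines}}
            for trait in sorted(grid)
        ]
        bundle["trait_grid"] = pd.DataFrame(grid_rows, columns=["trait", *pipelines])
        bundle["enrichment_records"] = pd.DataFrame(rec_rows)
    return bundle
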