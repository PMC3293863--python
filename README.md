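# cohortcluster

Robustness evaluation of unsupervised patient stratification from routine
blood biomarkers: pre-processing variants × clustering algorithms, cluster
quality under dropout resampling, classifier projection of clusters onto a
second cohort, and cross-cohort validated trait-enrichment accounting —
exercised end to end on synthetic cohort pairs that emulate a large adult
survey extract (≈40 mixed-unit markers, right-skewed markers, linear age
effects, latent subgroups, ≈19 binary health/lifestyle traits).

## Pipeline

1. **synth** — paired training/validation cohort generator with planted
   subgroups, age effects and trait–subgroup odds ratios, plus a truth
   record for scoring.
2. **preprocess** — four variants: `raw`, `norm_transform` (skewness-gated
   natural log), `zscore`, `age_adjust_zscore` (linear age correction
   `V′ = V − (a·age + b) + m`, gated at p < 0.05 and |r| > 0.1, then
   Z-score).
3. **cluster** — a CLICK-style graph clustering (Pearson similarity,
   EM-fitted mates/non-mates mixture, LLR edge weights, recursive splitting
   with a Stoer–Wagner kernel test, singleton adoption, kernel merging; may
   leave samples UNCLASSIFIED), K-means, and a batch SOM, under one
   assignment contract. K for K-means/SOM comes from the CLICK run of the
   same variant.
4. **quality** — homogeneity H_A, separation S_A, the H_A − S_A score, a 3%
   dropout resampling summary (N = 10), and Student's t comparison of
   pipelines.
5. **project** — feed-forward classifier (or nearest-centroid) trained on
   training-cohort labels, assigning every validation sample to a training
   cluster.
6. **enrich** — per-(cluster, trait) hypergeometric over-representation
   (traits gated at ≥ 30 positives, p < 0.05), enrichment factors, and
   cross-cohort validated-enrichment bookkeeping (valid/total, distinct,
   validated clusters, pipeline enrichment factor).
7. **cli / experiment** — the full variants × algorithms grid from a YAML
   config, emitting quality/validation/trait-grid/record tables and a run
   log, bit-identically reproducible under a fixed seed.

## CLI

```bash
# write a synthetic cohort pair + truth record
cohortcluster synth --seed 1 --out data/

# run the full experiment grid from a config
cohortcluster run --config examples/experiment.yaml --seed 1 --out results/

# standalone enrichment of an existing labeling
cohortcluster enrich --labels labels.csv --traits traits.csv --out enrich.csv

# standalone quality report
cohortcluster quality --cohort cohort.csv --labels labels.csv --variant zscore
```

`run` writes `quality_table.csv` (per-pipeline K and H_A−S_A, resampled
mean ± SD for training, projected score for validation),
`validation_table.csv` (valid/total enrichments, distinct traits, validated
clusters, pipeline factor), `trait_grid.csv` (validated trait × pipeline
matrix), `enrichment_records.csv` (every test), `run_log.txt` and
`resolved_config.yaml`. Minimal config:

```yaml
mode: synthetic          # or "files" with train/valid cohort+trait CSV paths
variants: [raw, norm_transform, zscore, age_adjust_zscore]
algorithms: [click, kmeans, som]
resample_frac: 0.03
resample_reps: 10
seed: 1
outdir: results
```

Cohort CSVs have columns `sample_id, age_years, <marker...>`; trait CSVs
have `sample_id, <trait...>` with values 0/1 or empty for unknown. Subset
analyses (e.g. restricting to a disease-positive stratum with extra
markers) are plain data operations: filter the cohort CSV rows and add the
marker columns, no dedicated code path. An adapter for an external survey
source is intentionally out of scope; export its tables to the CSV layout
above.

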