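# Full 12-combination experiment grid on the packaged synthetic default
# cohort pair.  Replace `mode: synthetic` with `mode: files` plus the four
# CSV paths to run on exported survey data.
mode: synthetic
variants: [raw, norm_transform, zscore, age_adjust_zscore]
algorithms: [click, kmeans, som]
resample_frac: 0.03
resample_reps: 10
enrichment_alpha: 0.05
enrichment_min_positives: 30
projector_method: mlp
seed: 1
outdir: results
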