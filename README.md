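# pairdiff

A pairmate representational-similarity pipeline for event-related fMRI
designs, runnable end to end on fully synthetic data.

The package covers six stages:

1. **Experiment design** (`pairdiff.design`) — seeded generation of a
   72-scene / 36-pairmate-pair stimulus set (12 pairs per learning
   condition, balanced indoor/outdoor), scanner runs of 72 scene + 24
   null trials (4 s trials, TR 2 s, 8.33% target flags, pairmates in
   opposite half-blocks), and study/test learning schedules with
   pairmate/nonpairmate foil rules.
2. **Synthetic data** (`pairdiff.synth`) — latent scene representations
   as a Gaussian factor model with per-condition pairmate coupling
   (including repulsion past orthogonality), unit-dropout/repulsion
   differentiation, a double-gamma-HRF forward BOLD simulator with
   AR(1) noise and drift, and a behaviour generator whose log-odds of a
   correct outcome depend on the pair's representational overlap.
3. **Pattern estimation** (`pairdiff.estimation`) — design matrices
   (impulse or boxcar events), Gaussian-weighted local-linear high-pass
   filtering, OLS / AR(1)-prewhitened GLM fitting with fixed-effects
   run combination, localizer contrasts, and threshold/tercile voxel
   selection.
4. **Similarity analysis** (`pairdiff.rsa`) — the 36 x 36 cross-set
   Fisher-z correlation matrix, per-pair difference scores (pairmate
   similarity minus mean same-condition nonpairmate similarity),
   condition summaries, and classical (Torgerson) MDS embeddings.
5. **Inference** (`pairdiff.inference`) — maximum-likelihood
   mixed-effects logistic regression (adaptive Gauss–Hermite for random
   intercepts, Laplace for random slopes) with likelihood-ratio tests;
   paired t / repeated-measures ANOVA with Wilcoxon/Friedman fallbacks
   and Shapiro/Mauchly screening; L2-logistic face-evidence scoring.
6. **Pipeline + CLI** (`pairdiff.pipeline`, `pairdiff.cli`) —
   config-driven, file-based stage orchestration with provenance and
   figure generation.

## CLI

```sh
# full pipeline (design -> simulate -> estimate -> rsa -> infer -> report)
pairdiff run --config cfg.yaml --seed 1 --out out/ --subjects 6

# or stage by stage into the same output directory
pairdiff design  --out out/
pairdiff simulate --out out/
pairdiff estimate --out out/
pairdiff rsa      --out out/
pairdiff infer    --out out/
pairdiff report   --out out/
```

Configs are YAML, schema-validated (unknown keys rejected), and every
random stage derives its stream from the single top-level `seed`. A
minimal config is just `seed: 1`; see `pairdiff.config.PipelineConfig`
for all sections (design geometry, per-ROI coupling models, noise, GLM,
RSA and inference options).

Outputs per stage: stimulus sets and learning schedules as CSV, events
as BIDS-style TSV, BOLD runs as NIfTI with JSON sidecars, t-map/beta
pattern tables as CSV, similarity matrices and difference scores as
CSV, model fits as CSV/JSON, and figures under `report/`.

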