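# longdbn

Temporal alignment and constrained dynamic Bayesian network (DBN)
inference for longitudinal multi-omics microbiome studies.

Given per-omic longitudinal feature tables (taxa, microbial genes,
metabolites), a sample metadata table, and optional static host-gene
and environmental variables, the pipeline:

1. **Preprocesses** each layer: relative (sum-to-one) normalization or
   additive log-ratio transform against a reference taxon, metabolite
   mean/variance filtering, removal of subjects with too few time
   points, and top-variance host-gene selection.
2. **Fits cubic B-spline curves** per subject/feature (GCV-smoothed or
   exactly interpolating) to handle irregular sampling.
3. **Temporally aligns** subjects with a linear warp `tau(t) = a*t + b`
   against an automatically selected reference subject, drops subjects
   whose alignment error exceeds `mu + 2*delta`, and propagates each
   warp to all of a subject's omic layers.
4. **Learns a two-slice conditional linear-Gaussian DBN** by
   BIC-scored greedy hill climbing, restricted by a typed constraint
   matrix (`skeleton` or `augmented` presets, or a custom JSON matrix),
   initialized with inter-slice self-loops and capped at a maximum
   number of parents per node. Edge confidence comes from a
   subject-level bootstrap (support = fraction of repetitions
   containing the edge; coefficients averaged).
5. **Evaluates** the model by leave-one-subject-out forward prediction
   (mean absolute error of renormalized compositions) and by in-silico
   edge validation against (parent, child) interaction databases:
   precision plus an exact Poisson-binomial tail probability, compared
   to size-matched random networks.

A seeded synthetic generator (`longdbn.synthetic`) produces datasets
with a known ground-truth network, per-subject warps, and matching
validation databases, so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic dataset (layer TSVs + metadata + truth network)
longdbn simulate --seed 1 --out data/

# emit a constraint preset
longdbn constraints --preset skeleton --out skeleton.json

# run the pipeline up to a given stage
longdbn align   --data data/ --out out/ --seed 1
longdbn learn   --data data/ --out out/ --seed 1
longdbn run     --data data/ --out out/ --seed 1 --db-tg tg_pairs.tsv
```

Every tunable has a dotted config key (see `longdbn.core_io.DEFAULTS`)
settable through a YAML/JSON file passed with `--config`; the effective
configuration is echoed to `config_effective.json` in the output
directory. Unknown keys are rejected. Identical configs and seeds
produce byte-identical network TSVs.

Artifacts: `warps.tsv` (subject, a, b, error, dropped flag),
`network.tsv` / `network.graphml` (edges with sign, lag, normalized
weight, bootstrap support), `prediction.tsv` (per-subject MAE),
`validation.tsv` (per-threshold precision and Poisson-binomial tail
with random-network baselines).

## Layout

| module | contents |
| --- | --- |
| `longdbn.core_io` | dataset/network domain types, TSV readers/writers, GraphML/SIF export, config |
| `longdbn.preprocess` | normalization and filtering rules |
| `longdbn.trajectories` | B-spline curves and uniform resampling |
| `longdbn.alignment` | pairwise warp search, reference selection, error filtering, warp propagation |
| `longdbn.constraints` | typed edge-constraint matrices and presets |
| `longdbn.dbn` | observation tables, Gaussian CPDs, BIC, greedy search, bootstrap, network summaries |
| `longdbn.evaluate` | leave-one-out prediction, validation databases, Poisson-binomial statistics, random-network null |
| `longdbn.synthetic` | ground-truth simulator and validation-database builder |
| `longdbn.cli` | `longdbn` subcommands and the end-to-end pipeline |
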