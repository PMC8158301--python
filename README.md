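# ubipattern

Expression-pattern discovery and per-sample scoring for tumor cohorts,
exercised end-to-end on synthetic data with planted ground truth. The
pipeline covers:

- **Synthetic data** (`ubipattern.synthetic`) — expression matrices with K
  latent patterns, positively/negatively loaded regulator genes,
  immune-signature genes, noise genes, and survival times whose hazard
  depends log-linearly on a planted per-sample score.
- **Preprocessing / DE** (`ubipattern.de`) — unscaled-MAD noise filter,
  per-gene Welch t-tests with Benjamini–Hochberg adjustment, and two-cohort
  intersection of significant regulators.
- **Consensus clustering** (`ubipattern.consensus`) — resampled k-means
  (Euclidean, gene-standardized) consensus matrices, CDF/delta-area model
  selection, and average-linkage pattern assignment with deterministic
  A/B/C naming.
- **Enrichment** (`ubipattern.enrichment`) — single-sample gene-set
  enrichment (rank-weighted ECDF statistic, exponent 0.25, optional global
  max–min normalization) plus one-vs-rest pattern characterization.
- **Signature score** (`ubipattern.score`) — Pearson correlation of genes
  with the ordinal pattern encoding, Boruta-style all-relevant selection
  (random-forest importances vs shuffled shadow features, binomial
  confirm/reject), and the per-sample score PC1(A) − PC1(B) with
  deterministic PC1 orientation.
- **Survival** (`ubipattern.survival`) — Kaplan–Meier curves, k-group
  log-rank tests, Cox proportional hazards (Breslow ties, Newton–Raphson),
  and minimal-p cutpoint search with a permanent selection-bias flag.
- **Drug response** (`ubipattern.drug`) — ridge-regression IC50 models with
  cross-validated penalty selection, applied to tumor expression.
- **Pipeline/CLI** (`ubipattern.pipeline`, `ubipattern.cli`) — YAML-driven
  orchestration with TSV/GMT I/O and a hashed JSON run manifest;
  byte-identical outputs under a fixed seed.

## CLI

```sh
ubipattern simulate --n-samples 200 --seed 7 --out data/
ubipattern de --expr expr.tsv --groups groups.tsv --out de.tsv
ubipattern cluster --expr regulators.tsv --kmin 2 --kmax 6 --reps 1000 --seed 7 --out clusters/
ubipattern enrich --expr expr.tsv --gmt sets.gmt --out enrichment.tsv
ubipattern score --expr regulators.tsv --labels clusters/patterns.tsv --seed 7 --out score/
ubipattern survival --score score/score.tsv --clinical clinical.tsv --adjust age,stage --out surv/
ubipattern drug --train-expr cells.tsv --train-ic50 ic50.tsv --tumor-expr expr.tsv --out pred.tsv
ubipattern run --config pipeline.yaml --out run/
```

Exit codes: 0 success, 2 validation problem, 3 stage failure. Expression
files are genes × samples TSV (first column gene ids, header sample ids);
gene sets are GMT; clinical tables are TSV with `sample`, `time_months`,
`event` and covariate columns.

A minimal `pipeline.yaml`:

```yaml
seed: 7
synthetic:
  n_samples: 200
  n_patterns: 3
  n_regulator_genes: 300
  n_noise_genes: 100
  pattern_separation: 3.0
cluster: {k_min: 2, k_max: 6, reps: 100}
```

Real cohorts can be supplied instead of the `synthetic` block through an
`inputs:` block pointing at expression/clinical/GMT files.

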