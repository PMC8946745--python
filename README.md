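# sparseprs

Phenome-style sparse polygenic risk score (PRS) analysis as a reusable,
fully simulatable pipeline:

- **`sparseprs.simulate`** — multi-population diploid genotypes under a
  Balding–Nichols allele-frequency drift model with block-copula LD,
  variant annotations (consequence group, ClinVar class, allelotype flag),
  covariates, and quantitative or liability-threshold binary phenotypes
  with known SNP heritability.
- **`sparseprs.annotate_qc`** — variant QC (missingness, MAF, exact
  Hardy–Weinberg test, MHC exclusion), penalty-factor assignment
  (0.5 / 0.75 / 1.0 by pathogenicity and predicted consequence), and HLA
  dosage rounding.
- **`sparseprs.prs_fit`** — the core engine: a batch-screening iterative
  lasso for L1-penalized GLMs (gaussian/binomial) over wide genotype
  matrices with unpenalized covariates and per-variant penalty factors.
  Candidate variants enter the active set in gradient-ranked batches and
  every solution is KKT-certified against the full variant set. Sparsity is
  chosen on a validation split; the final model is refit on the combined
  score-development set and de-standardized to per-allele weights.
- **`sparseprs.score_eval`** — PRS computation from score files, covariate-
  only and full GLMs, R² with approximate-SE CI, Nagelkerke and Tjur
  pseudo-R², AUC with DeLong CI, incremental performance, and the strict
  Bonferroni significance rule (p < 0.05/2000).
- **`sparseprs.heritability`** — per-variant association scan (exact
  residualized OLS, or per-variant logistic with a score-test fallback),
  windowed LD scores with the small-sample r² correction, and LD score
  regression with block-jackknife standard errors.
- **`sparseprs.phenome_report`** — model-size vs incremental-performance
  Spearman correlation, enrichment of medically relevant alleles among
  selected variants, percentile-bin odds ratios against the 40–60th
  percentile bin, and through-origin cross-population transferability
  slopes.
- **`sparseprs.io` / `sparseprs.pipeline` / `sparseprs.cli`** — PLINK 1
  `.bed/.bim/.fam` reader/writer, ID/A1/BETA score files, TSV conventions,
  and a stage-composable pipeline.

## CLI

Each stage reads and writes a single artifact directory, so subcommands
compose to the same result as `run-all`:

```sh
sparseprs run-all --config config.yaml
sparseprs simulate --config config.yaml   # or stage by stage:
sparseprs qc --config config.yaml
sparseprs fit --config config.yaml
sparseprs score --config config.yaml
sparseprs evaluate --config config.yaml
sparseprs h2 --config config.yaml
sparseprs report --config config.yaml
```

Example `config.yaml`:

```yaml
output_dir: runs/demo
seed: 1
trait_name: trait1
simulation:
  n_per_population: {dev: 2000, other: 500}
  m_variants: 1000
  n_causal: 30
  h2_true: 0.5
  fst_per_population: {dev: 0.0, other: 0.1}
fit:
  n_lambda: 30
  batch_size: 100
  early_stop_patience: 5
```

Outputs include the QC report, per-λ path log, the score file
(`score.tsv` + JSON sidecar with covariate coefficients), per-population
evaluation (S6-style), GWAS and heritability tables (S7-style), and the
phenome summary.

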