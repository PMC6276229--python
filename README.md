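# proteoconcord

Integrated protein–mRNA concordance analysis for paired tumor / adjacent-normal
cohorts, from spectral-count preprocessing through survival association and
consensus-NMF subtyping, with a first-class synthetic-cohort generator used by
the test suite for recovery experiments.

## What it does

- **io_config** — typed readers/writers for the pipeline's tabular formats:
  features × samples TSV matrices, clinical CSV, GMT gene sets, pair maps,
  one-id-per-line annotation lists, YAML run configuration.
- **synthetic_data** — paired tumor/normal proteome + transcriptome cohorts:
  negative-binomial spectral counts with abundance-dependent detection
  dropout, log-normal mRNA intensities, per-sample protein–mRNA coupling
  calibrated on the Spearman scale against the actual scoring path, an
  asymmetric differential tail, a 3'UTR-flagged subset with protein-only
  upregulation, coupling-graded survival hazard, planted
  concordance-enriched pathways, and a two-block tumor structure; plus a
  ground-truth record for recovery tests.
- **preprocess** — two-rule feature filter (peptide support, detection
  coverage), median-of-ratios size factors, shrunken log2 transform,
  per-feature negative-binomial Wald tests, paired Wilcoxon signed-rank,
  Benjamini–Hochberg adjustment.
- **concordance** — tie-corrected Spearman; within-sample (per-sample global
  rho) and across-subject (per-pair) concordance; rank-sum / Kruskal–Wallis
  group comparisons; abundance/coverage/label stratifications; random-subset
  robustness; covariate-adjusted association (OLS + partial correlation).
- **enrichment** — GSEA-style pre-ranked weighted-KS enrichment with a
  feature-label permutation null and NES, and two-sample KS enrichment of
  gene sets in per-pair concordance.
- **survival_scores** — 11-gene proliferation metagene, quantile-based
  concordance groups, Kaplan–Meier, log-rank, Cox regression (Efron ties via
  lifelines) including trend coding and covariate adjustment, Fisher's exact
  test.
- **nmf_cluster** — MAD-based feature selection, multiplicative-update KL-NMF,
  consensus clustering over K with cophenetic model selection, group
  composition tests.
- **utr_analysis** — flagged-set vs background paired fold-change contrast
  (protein and mRNA), rank-sum and signed-rank variants.

## Command line

Each subcommand reads a YAML config (`--config`), writes to `--out`, and
records the resolved config + seed:

```bash
proteoconcord simulate    --config cfg.yaml --out run/   # cohort + truth
proteoconcord preprocess  --config cfg.yaml --out run/   # filter, rlog, DE
proteoconcord concordance --config cfg.yaml --out run/   # rho + group tests
proteoconcord enrich      --config cfg.yaml --out run/   # pre-ranked + KS
proteoconcord survival    --config cfg.yaml --out run/   # KM, log-rank, Cox
proteoconcord nmf         --config cfg.yaml --out run/   # consensus NMF
proteoconcord utr         --config cfg.yaml --out run/   # fold contrast
proteoconcord all         --config cfg.yaml --out run/   # the whole chain
```

A minimal config:

```yaml
seed: 7
simulate: {n_genes: 1000, n_tumors: 30, n_normals: 20}
enrichment: {n_perm: 1000}
nmf: {k_min: 2, k_max: 5, n_restarts: 20}
```

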