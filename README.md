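# oncosubtype

Immune-subtype discovery and characterization for tumor expression
cohorts.

Many tumors respond to immune-checkpoint inhibitors only in a minority of
patients, and the immune state of the tumor microenvironment is a leading
explanation. `oncosubtype` implements the full analysis arc used to split
an expression cohort into immune subtypes and characterize them:

1. **Prognostic immune-gene screen** — univariate Cox proportional-hazards
   regression (Efron ties) of each immune-related gene against overall
   survival, keeping genes with Wald p < 0.05 and unscaled median absolute
   deviation > 0.5.
2. **Consensus NMF subtyping** — Brunet multiplicative-update NMF
   minimizing the Kullback–Leibler divergence D(A‖WH) on the screened
   gene × sample matrix, repeated over random restarts; the consensus
   matrix of co-clustering fractions yields the cophenetic correlation,
   dispersion and silhouette, and the rank k with the highest cophenetic
   coefficient is selected. Cluster `sub1` is, by convention, the
   immune-enriched subtype.
3. **Immune scoring** — single-sample GSEA (ssGSEA) over a 28-cell-type
   panel; stromal/immune/ESTIMATE scores (ESTIMATE = stromal + immune);
   immune and T-cell infiltration scores (IIS/TIS, means of cell-type
   NES); cytolytic activity CYT = √(GZMA·PRF1); an 18-gene
   antigen-processing-machinery (APM) score min–max normalized to [0,1];
   tumor mutational burden (nonsynonymous variants per Mb from a MAF);
   checkpoint / interferon-γ / CD8 expression signatures; Wilcoxon
   rank-sum group tests and the r > 0.5 & p < 0.05 strong-correlation
   rule.
4. **DEG / GSEA contrast** — Mann–Whitney differential expression with
   Benjamini–Hochberg FDR (DEG ⇔ p < 0.01 ∧ FDR < 0.05 ∧ |log2FC| > 1)
   and preranked GSEA (Subramanian running sum, gene-set permutation
   null, sign-stratified FDR).
5. **Mutation landscape** — per-subtype mutated-gene frequencies, variant
   classification counts, the six-class pyrimidine-collapsed SNV spectrum,
   and chi-square / Fisher driver-gene comparisons.
6. **Subtype classifier** — a random forest (mtry = 2, 500 trees) on
   survival-screened DEGs with repeated tenfold cross-validated
   variable-count selection, ROC/AUC evaluation and cross-cohort
   prediction via per-gene rank normalization.
7. **Subclass mapping** — mutual marker-gene enrichment (SubMap-style)
   between the discovered subtypes and an immunotherapy cohort's
   responder / non-responder groups, with permutation p-values combined
   across directions by Fisher's method and Bonferroni adjustment.
8. **Co-expression modules** — WGCNA-style unsigned network: soft
   threshold by scale-free fit, topological overlap matrix, average-
   linkage module detection, module eigengenes (first principal
   component), gene significance / module membership, and cross-cohort
   hub-gene intersection.

A synthetic-cohort generator (`oncosubtype.simulate`) produces
negative-binomial counts with a planted two-subtype immune program,
subtype-linked exponential survival, a subtype-linked mutation burden and
a paired immunotherapy cohort, so the entire pipeline is testable without
any external download.

## Worked example

```python
from oncosubtype import io, scoring
from oncosubtype.nmf import assign_subtypes
from oncosubtype.simulate import default_config, simulate_cohort
from oncosubtype.survival import km_logrank, screen_irgs

cohort = simulate_cohort(default_config(seed=1))

screen = screen_irgs(cohort.expression, cohort.clinical,
                     cohort.expression.gene_ids)
print(f"prognostic genes (p<0.05): {len(screen.retained_genes)}, "
      f"kept after MAD filter: {len(screen.mad_retained_genes)}")

A = io.log2cpm(cohort.expression, genes=screen.mad_retained_genes)
k, subtypes, summary = assign_subtypes(A, rank_range=range(2, 7),
                                       n_restarts=30, seed=1)
print(f"selected rank k={k}")
print(summary.metrics_frame().round(3))

surv = cohort.clinical.survival("os")
lr = km_logrank(subtypes.labels.loc[surv.index], surv["time"], surv["event"])
print(f"log-rank p between subtypes: {lr['p']:.2e}")

tmb = scoring.compute_tmb(cohort.maf, cohort_samples=cohort.expression.sample_ids)
lab = subtypes.labels
print(f"TMB sub1: {tmb[lab=='sub1'].mean():.2f}, "
      f"sub2: {tmb[lab=='sub2'].mean():.2f} mut/Mb")
```

prints

```
prognostic genes (p<0.05): 133, kept after MAD filter: 109
selected rank k=2
      cophenetic  dispersion  silhouette
rank
2          1.000       1.000       1.000
3          0.987       0.750       0.787
4          0.960       0.600       0.497
5          0.958       0.567       0.382
6          0.947       0.556       0.234
log-rank p between subtypes: 5.00e-04
TMB sub1: 5.93, sub2: 1.99 mut/Mb
```

The cophenetic coefficient is maximal at k = 2, so the cohort splits into
two subtypes; the split separates survival (log-rank p = 5×10⁻⁴) and the
immune-enriched subtype `sub1` carries roughly threefold the mutation
burden of `sub2` — the pattern the pipeline is designed to surface.

## Command line

```sh
# write three synthetic cohorts + an immunotherapy cohort + a demo config
oncosubtype simulate --outdir demo --seed 7 --n-cohorts 3

# run the full pipeline (all eight stages, deterministic given the seed)
oncosubtype run --config demo/demo.yaml --outdir out

# re-run a single stage from cached upstream tables
oncosubtype stage dge --config demo/demo.yaml --outdir out
```

`run` writes plain TSV tables per stage (subtype assignments, rank
metrics, score tables and tests, DEG/GSEA tables, mutation summaries,
classifier performance, SubMap p-value matrices, module assignments and
hub genes) plus `manifest.json` recording the config hash, per-stage
seeds and timings. Re-running with the same config reproduces every table
byte for byte.

Estimator-style entry points (`NMFSubtyper`, `SSGSEAScorer`,
`SubtypeClassifier`, `CoexpressionNetwork`) expose the core steps with
scikit-learn `fit`/`predict`/`transform` semantics for use in custom
scripts.

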