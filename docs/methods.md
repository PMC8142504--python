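# Methods

This note documents the models and procedures implemented in
`oncosubtype`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices a
maintainer would want to know.

## Expression scales and normalization

Raw counts are converted to CPM with total-count library sizes (no TMM)
and log-transformed as log2(CPM+1); array intensities are used as-is.
Library sizes are **always computed on the full matrix**: normalizing a
gene subset by its own column sums would let a planted (or biological)
program cancel its own signal — with a 100-gene program occupying ~20% of
a 500-gene library this effect is large, and `io.cpm`/`io.log2cpm`
therefore take an optional `genes=` argument that subsets only after
normalization.

## Prognostic screen

Each candidate gene is fit in a univariate Cox proportional-hazards model
(Efron tie handling) against overall survival on the log2(CPM+1) scale;
the log scale stabilizes the per-unit hazard ratio across the expression
range. Multi-covariate fits go through lifelines; the per-gene screen
uses a vectorised scalar-Newton solver (one β per gene, shared risk-set
suffix sums, step-halving, |β| capped at 20 under monotone likelihood)
that maximises the same Efron partial likelihood — it is cross-checked
against lifelines in the tests. Genes with two-sided Wald p < 0.05 are
retained; of those, genes with unscaled MAD ≤ 0.5 (median(|x−median(x)|),
no 1.4826 consistency constant) are removed before clustering. The screen
and the MAD filter run per cohort on that cohort's own scale.

## Consensus NMF subtyping

The screened gene × sample matrix A is factorised as A ≈ WH by Brunet
multiplicative KL updates, W and H initialised uniform(0,1] from an
explicit seed. Updates stop when the sample connectivity (argmax over the
columns of H) is unchanged for 40 consecutive checks performed every 10
iterations, or at 2000 iterations. The KL objective is recorded at every
check and is non-increasing by construction (asserted in tests).

**Input centering.** By default each gene's cohort minimum is subtracted
from its log2(CPM+1) values before factorisation (`center="min"`). Log
expression carries a large shared offset (genes sit at 8–14 log2 units);
KL-NMF spends its components fitting that offset, and the cluster readout
then tracks incidental structure — in development the raw-scale readout
recovered the planted subtypes with ARI anywhere between 0.2 and 1.0
across seeds, while the baseline-subtracted input recovers them
reliably. The subtraction keeps the matrix nonnegative and the scale
interpretable (expression above the gene's cohort floor); `center=None`
restores the raw behaviour.

Consensus: each rank k in 2..6 is run with `n_restarts` random restarts
(seed = base seed + restart index); C[i,j] is the fraction of restarts in
which samples i and j co-cluster. Rank-selection metrics: cophenetic
correlation (Pearson correlation between the off-diagonal consensus
distances 1−C and the cophenetic distances of their average-linkage
dendrogram), dispersion (mean of 4(C−½)²) and mean silhouette of the
best-restart labels under distance 1−C. The selected k maximises the
cophenetic coefficient (ties → smaller k). Final labels come from the
best-objective restart (consensus is used only for the metrics), and
clusters are renamed so `sub1` has the highest mean immune score
(per-sample mean of A as fallback). 30 restarts is the default problem
size for tests and the acceptance script; the restart count is a plain
parameter and larger values only sharpen the consensus.

## Immune scores

* **ssGSEA**: per sample, genes are ranked by expression (rank N =
  highest; ties broken by lexicographic gene id, making the statistic
  exactly invariant under strictly increasing transforms). With in-set
  weights rank^α (α = 0.25, the field's default), the enrichment score is
  the sum over ranked positions of the weighted in-set ECDF minus the
  uniform out-of-set ECDF. NES divides ES by the range (max − min) of all
  ES values of the run. Note the range normalisation bounds NES in
  [−1, 1] only when the ES values span zero; when all ES share a sign the
  normalised values can exceed 1 in magnitude, so no such bound is
  asserted.
* **ESTIMATE-style scores**: stromal and immune ssGSEA scores on supplied
  panels; the ESTIMATE score is exactly their sum.
* **IIS / TIS**: means of cell-type NES over the adaptive+innate panel
  (28 types) and over the eight T-cell types (activated CD8 T, T helper,
  effector memory T, central memory T, Th1, Th2, Th17, Treg).
* **CYT**: √((GZMA+0.01)(PRF1+0.01)) on the linear CPM scale; the 0.01
  offset handles zeros.
* **APM**: ssGSEA enrichment of the 18-gene antigen-processing panel,
  min–max normalised to [0,1] across the cohort. (This is a deliberate
  rank-based stand-in for the Gaussian-kernel GSVA variant: deterministic
  and transform-invariant.)
* **TMB**: nonsynonymous variants (Missense, Nonsense, Nonstop,
  Translation_Start_Site, Splice_Site, Frame_Shift_Ins/Del,
  In_Frame_Ins/Del) per megabase; the exome footprint defaults to 35 Mb
  and is configurable, as capture footprints vary by kit.
* **Checkpoint signature**: {CD274, CTLA4, HAVCR2, LAG3, PDCD1,
  PDCD1LG2}; a literal variant with "HAVCR"/"LA3" is selectable by
  config for comparability with sources that print the split names.
* **Wilcoxon**: exact null when both groups have n ≤ 25 and no ties;
  otherwise tie-corrected normal approximation with continuity
  correction.

## DEG / GSEA

Differential expression uses a two-sided Mann–Whitney test on
log2(CPM+1) with a mean-CPM fold change (pseudocount 1) — an
assumption-light, self-contained choice rather than a negative-binomial
exact test; BH adjustment via statsmodels. The DEG flag is the strict
conjunction p < 0.01 ∧ FDR < 0.05 ∧ |log2FC| > 1. Preranked GSEA ranks
genes by log2FC descending (ties by gene id), uses the weighted running
sum (weight 1), a gene-set permutation null (appropriate for a preranked
list), add-one permutation p-values against the same-sign null, NES = ES
divided by the mean |null ES| of matching sign, and the sign-stratified
null/observed tail-ratio FDR.

## Classifier

Candidate genes are DEGs with univariate Cox p < 0.05 on overall
survival. Features are per-gene within-cohort rank-normalised values in
[0,1] (computed identically at training and prediction time), which makes
an RNA-seq-trained forest applicable to array cohorts. Genes are ranked
by impurity importance from a forest on all candidates; repeated
stratified tenfold CV evaluates nested importance-ranked subsets, and the
subset with minimum mean error (ties → fewer genes) is refit as the final
model (mtry = 2, 500 trees by default). Missing genes at prediction time
are imputed at the training median (error if more than half are missing).
AUC is the trapezoid over the empirical ROC, identical to concordant-pair
counting.

## Subclass mapping

Both cohorts are reduced to their common genes and converted to
within-sample gene ranks. Markers of subtype i in cohort A are the top
100 genes by signal-to-noise ratio (σ floored at max(0.2|μ|, 0.2)); their
enrichment near the top of cohort B's subtype-j SNR ranking is scored
with the unweighted KS running sum. Permutation p-values (label
permutations of the opposite cohort, add-one correction) from the two
directions are combined by Fisher's method (χ²₄) and Bonferroni-adjusted
by the number of subtype pairs.

## Co-expression modules

Unsigned network: adjacency = |Pearson r|^β. The scale-free fit regresses
log10 degree **density** on log10 mean degree over 10 equal-occupancy
bins (with equal-occupancy bins the raw per-bin fraction is constant, so
a density — fraction divided by bin width — is required); R² is signed
negative when the slope is positive. β is the smallest power reaching
R² ≥ 0.8 among powers whose mean connectivity stays above a floor
(default 2.0); if none reaches the target, the argmax-R² usable power is
taken with a warning. The connectivity floor exists because on strongly
modular data R² keeps rising with β long after the network has dissolved
into singletons; an unconstrained argmax picks β ≈ 20 with mean
connectivity < 0.1 and module detection degenerates.

TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij) with unit diagonal.
Modules come from an average-linkage tree on 1−TOM cut statically at the
smallest candidate height (fractions 0.5–0.99 of the maximum merge
height) that yields ≥ 2 modules of at least `min_module_size` genes —
a deliberate simplification of the dynamic tree cut; genes in undersized
clusters are left unassigned (label 0), and no eigengene-similarity
merging is performed. Eigengenes are the unit-norm first right singular
vector of the standardized module matrix, sign-oriented towards positive
mean correlation with the module genes. Hubs are genes of the most
trait-correlated module with |MM| ≥ 0.8 and GS ≥ 0.5 (configurable —
no published thresholds exist for this step), intersected across
cohorts. Because a co-regulated program can split into sub-modules, the
best-module choice may differ between cohorts and the intersection can
legitimately be small or empty; the per-cohort hub lists carry the
provenance.

## Synthetic cohorts

The generator emulates a small bulk RNA-seq study:

* counts ~ NB(μ, α) with variance μ + αμ², α = 0.2; baseline log2 means
  uniform on [3, 10] (program genes on [3, 7], keeping the planted
  programs a realistically small fraction of the library — at equal
  baselines a 100-gene program reaches ~50% of a 500-gene library in the
  enriched subtype and CPM normalisation absorbs its covariation);
* library sizes log-normal (σ = 0.3) so CPM normalisation matters;
* a 100-gene immune program shifted +2 log2 units in `sub1` and a 60-gene
  second program shifted −1.5 log2 units, each carrying a shared latent
  factor (σ = 0.6 log2) with random ±1 gene loadings — the signed
  loadings give the DEG set a realistic multi-module correlation
  structure without moving the program means, so subtype recovery and
  module detection can both be exercised;
* known marker symbols (GZMA, PRF1, CD8A/B, the checkpoint and
  interferon-γ genes) are planted inside the program and the 18 APM genes
  in the background, so every score formula applies verbatim;
* overall survival exponential with hazard 0.03/month for `sub1` and
  hazard ratio 3 for `sub2`, independent exponential censoring calibrated
  to 25% censored (the study system shows a strong survival split between
  immune subtypes; weaker settings starve the per-gene screen at n = 60);
* per-sample nonsynonymous mutation counts Poisson(TMB × 35 Mb) with
  mean TMB 6 vs 2 mut/Mb, variants assigned 80% to a 50-gene background
  panel and 20% to a driver list with subtype-specific enrichment, a C>T
  transition-biased substitution spectrum, and extra Silent variants at
  30% of the nonsynonymous rate;
* an immunotherapy cohort sharing the same gene universe in which
  responders carry the `sub1` program.

Not emulated: batch effects, tumor purity, covariate structure
(stage/age effects on survival), isoform-level signal, and microarray
noise characteristics. Passing tests therefore demonstrate correctness
and calibration of the machinery under the generative assumptions, not
robustness to real-data artifacts.

## Determinism and numerics

Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from one master seed, and a re-run with the same config
reproduces all output tables byte-identically (floats are written with
`%.10g`). KL updates guard denominators with the smallest positive
float; the Cox solver uses lifelines with its convergence precision
tightened to 1e-9 so the optimum agrees with a grid-search oracle to
1e-4. Permutation p-values use add-one correction and are never zero.
Ties are always broken deterministically (lexicographic gene ids in
rankings, stable sorts elsewhere).
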