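# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the known limits of what the test suite demonstrates.

## Count models

**Pseudo-bulk differential expression.** Gene counts are summed per
(cluster, biological replicate); replicates contributing ≤20 nuclei to a
cluster are excluded, and a cluster with no eligible replicate in either sex
is skipped and reported. Genes enter the analysis if they have >1 count in
≥5 nuclei; ids matching a configurable "predicted gene" pattern (defaults:
`Gm`-numeric and `…Rik`) are dropped. Size factors are the median-of-ratios
estimator over genes nonzero in every column, renormalised to geometric mean
1; a matrix with no such gene raises an error pointing at a pseudo-reference
fallback rather than silently changing estimator. The per-gene model is a
negative-binomial GLM with log link and `log(size factor)` offset,
`Var[y] = μ + αμ²`.

*Dispersion.* α is estimated per gene by Pearson-χ² matching: solve
`Σ_s (y−μ)² / (μ + αμ²) = S − P` with Newton steps nested inside refits of
μ, floored at 1e-8. This is a moment-type estimator (no empirical-Bayes
shrinkage across genes) but is far less downward-biased at small sample
counts than the plain residual-moment formula, which matters directly for
type-I error.

*Inference.* The sex (or group) coefficient is tested by Wald statistic
referred to a **t distribution with S − P degrees of freedom**; multi-
coefficient tests (ANOVA-like across conditions, sex × treatment
interaction) use the likelihood-ratio statistic referred to
**F(df, S − P)** via LR/df. Both choices account for the estimated
dispersion: with the normal/χ² references the tests are visibly
anti-conservative at n = 3–5 replicates, with t/F they are calibrated at
n = 8 per group (null simulations: KS uniformity p ≈ 0.15–0.5, type-I error
at the nominal 5%) and mildly *conservative* — never inflated — at the
n = 3–5 of typical designs. Fold changes are reported as log₂ without
shrinkage; the one-sided marker test replaces a shrinkage prior with an
explicit composite null H0: log₂FC ≤ threshold (Wald t, one-sided), which
reproduces the same decision behaviour at the quoted threshold of 2.

**Hurdle test (single cell).** Detection (count > 0) is modelled by a
logistic regression and expression given detection by a linear model on
log1p-normalised counts (scale 1e4), both with the group term plus
standardised continuous covariates (defaults: genes detected, total
counts). The two likelihood-ratio statistics are added and referred to χ²
with the summed df. Genes below 5% detection in both groups, or with
|log₂FC| of mean log-normalised expression below 0.2, are not tested.
Because the test treats cells as exchangeable, replicate-level variance
components inflate it (the usual pseudo-replication caveat); the null
calibration is therefore demonstrated on data without a replicate
component, and cluster-level claims in the package rest on the pseudo-bulk
test instead.

**Cluster merging.** A dendrogram over cluster mean profiles
(average-linkage on log-normalised means) is cut into terminal sibling
pairs; a pair merges when fewer than 10 genes pass: adjusted p < 0.05,
|avg log₂FC| > 0.5, <10% detection in the negative cluster, >25% in the
positive cluster. Rounds repeat until no terminal pair merges, so the
procedure is idempotent. The DE engine behind the gate is pluggable; the
default is the hurdle test.

## Abundance

Per-replicate proportions over the included clusters (rows sum to 1);
replicates with zero cells in any required cluster are flagged for
exclusion. The test is a one-sided Wilcoxon rank-sum with **exact
enumeration over rank assignments** (midranks under ties, so the p-value
remains a valid permutation p-value) for n ≤ 20 pooled observations,
normal approximation with tie correction above. The tested direction is
configurable (default: male greater); BH runs across the cluster family.

## Chromatin states

The multi-condition NB test above feeds three procedures, all operating on
row-z-scaled CPM matrices (zero-variance rows dropped):

- *k*-means archetypes: Lloyd's algorithm, k = 4, `iter.max = 50`, 25
  restarts, fixed seed; one post-hoc pruning pass removes peaks with
  Pearson r < 0.8 to their assigned centroid, and centroids are recomputed
  from retained members (assign → prune, not iterated).
- NE-open / NE-close: complete-linkage Euclidean hierarchical clustering
  of the three neonatal group profiles (the defaults of the heatmap tool
  conventionally used; metric/linkage configurable), cut at k = 6; among
  the two largest clusters, one is labelled NE-open when its centroid has
  NV-male and E2-female accessibility above NV-female, NE-close for the
  mirror pattern; ties on size break toward the lower cluster index and
  degenerate patterns yield no label. Because a large planted class can
  split across dendrogram branches, the guaranteed property is label
  *precision* (labelled peaks have the right pattern), not recall of every
  class member — matching how the labels are defined.
- Sex-difference profiles: per-cluster male−female CPM differences at the
  supplied loci (clusters under 400 nuclei removed, clusters missing one
  sex excluded with a warning), row-z-scaled, k-means with k = 12.

Maintenance overlap is interval intersection (≥1 shared bp, 0-based
half-open throughout) between early-life regulated peaks and adult
sex-biased peaks, reported as a fraction of the early set.

## Motifs

Scanning scores log₂ odds of the position probability matrix
(pseudocount-regularised) against a zero-order background on both strands;
`N` scores as background (0 contribution). The null score distribution is
computed exactly by dynamic programming over scores discretised to
**1e-3 bits**, which bounds the p-value error by the mass within one grid
step of a threshold; p-values are tail sums, monotone in score, and the
default hit threshold is p ≤ 1e-4. Background peaks are matched per
foreground peak as nearest neighbours in standardised (GC fraction,
log mean accessibility) space, foreground excluded, sampling without
replacement within a peak (with replacement plus a warning when the pool
is exhausted). Enrichment is a one-sided Fisher exact test on peak-level
presence (≥1 hit), BH across motifs — an exact replacement for rank-based
enrichment statistics over the same question. Deviations follow the
chromVAR construction: expected motif counts per cell are
`depth_c × Σ_p f_p` with `f_p` the peak's share of total counts; the raw
deviation `(obs − exp)/exp` is z-scored against 50 (≥20 required)
matched background peak sets drawn from each motif peak's 50 nearest
neighbours under a fixed seed. Raw deviations are exactly zero for an
annotation covering all peaks and invariant to uniform depth scaling.

## TF screens

The R² ranking regresses per-cluster sex-DEG counts on the per-cluster
percentage of cells detecting the TF (detection = ≥1 count, the convention
used for the Esr1⁺ classification); R² is the squared Pearson correlation,
constant predictors score 0 with a flag, ties break by TF id. The
identity-regulator screen computes Pearson correlation between TF
expression and its motif deviation over cells (cluster-mean mode
available) and calls a regulator when r > 0.5 AND the TF's maximum
inter-cluster expression log₂FC is at or above the screened set's median.

## Linking

Candidate peak–gene pairs satisfy 2 kb ≤ |peak center − TSS| ≤ 1 Mb with
the peak accessible in ≥2% of cells; Pearson r gets a two-sided p from the
Fisher z transform and BH within each gene. The distance anchor is the
peak center (summit when present); signed distance is reported.
Regulatory potential is `Σ exp(−0.5 − 4Δ)` over peaks with
`Δ = |center − TSS|/d ≤ 1` (d = 500 kb default; the constants are
configurable). Association between a peak set and regulated genes is a
one-sided two-sample KS test on RP values ("regulated greater"),
up- and down-regulated sets tested separately.

## Cluster matching

Cells from both datasets are log-normalised over the supplied gene set and
rank-transformed per cell (a Spearman correlation network); only
cross-dataset edges are used, shifted to non-negative weights and
row-normalised. A query cell's vote for a reference cluster is its mean
connectivity to that cluster's cells, and the AUROC per (reference, query)
pair is the Mann-Whitney identity on the vote vector. Cross-dataset
variable genes are ranked by dispersion of log-normalised expression
standardised within mean-expression bins (bin count adapts to the gene
universe); genes must sit in the top half of both datasets' rankings and
are ordered by summed within-bin z-scores.

## Synthetic data

The generator emulates the *statistical structure* of multiome studies of
hormone-receptive neurons, never their content. Defaults describe one
study-scale dataset: 7 clusters × 2 sexes × 5 replicates × 42 nuclei
(~3,000 nuclei), 2,000 genes, 3,000 peaks on a 6-Mb single-chromosome toy
genome with evenly spaced TSSs (so distance-window logic is exactly
checkable). Counts are gamma-Poisson (NB) with lognormal gene means
(median 0.5/cell), lognormal gene-wise dispersion (median 0.05), lognormal
cell library factors (σ = 0.3) and per-(gene, replicate) biological noise
(σ = 0.15) — the component that gives pseudo-bulk columns realistic
overdispersion. Identity programs plant ~20 markers per cluster at
log₂FC 2.5; sex effects multiply cluster baselines (200 genes, |log₂FC|
1.5, random sign, 1–3 clusters each, drawn from the better-expressed half
so planted effects are detectable at this depth). Identity regulators are
well-expressed TFs boosted in one cluster; their motif peak sets follow the
TF's underlying log expression rate (coupling 0.8), while all other TFs
receive uncoupled random peak sets so screen precision is meaningful.
Cluster-restricted male-open loci occupy a strict subset of clusters
(a uniform sex effect would vanish under row scaling, as it should).
Peak–gene link pairs share a per-cell latent factor (coupling 0.6) and are
placed inside the 2 kb–1 Mb window. Bulk condition designs plant archetype
peaks as per-group mean multipliers (4-fold) with 3 replicates per group;
the neonatal class sizes are deliberately unequal (200/100/40/40) to
mirror the predominance of surge-opened regions. Per-cell QC metrics carry
a panel-external floor (the simulated genes are a panel, not a
transcriptome), so default-bound QC keeps healthy cells. Every truth-table
draw precedes every count draw, making the truth invariant to nuisance
parameters such as library size under a fixed seed; a fixed seed gives
byte-identical output.

What passing tests show — and what they do not: recovery and calibration
hold under NB noise with independent cells within replicates, no ambient
contamination, no doublets, no batch structure beyond replicate factors,
and cluster labels known. Real data violate several of these; in
particular, hurdle-test p-values on real clustered data inherit
pseudo-replication optimism, and per-cell link correlations are attenuated
by sparsity rather than Gaussian noise.

## Numerical choices and degenerate inputs

IRLS for the NB GLMs is vectorised across features (shared design, batched
p×p solves), clipped at |η| ≤ 30 with a 1e-10 ridge, tolerance 1e-8,
50 iterations. All-zero features return NA rather than estimates.
Intervals are 0-based half-open everywhere; 1-based dialects must be
converted at the reader. Recentring produces [summit − f, summit + f + 1)
(width 2f + 1), clipped at 0. QC bounds are strict inequalities — boundary
cells survive. BH propagates NaNs without counting them in m. Empty peak
sets are legal for intersection; k exceeding the row count, singular
designs, confounded covariates, overlapping gene sets and missing summits
raise errors naming the problem.

## Pipeline

`regulome run` executes simulate → QC → DE → abundance → states →
NE states → motifs → deviations/regulator screen → links → split-half
match → maintenance, with per-stage seeds derived from the master seed,
per-stage runtimes and a truth-recovery report in `manifest.json`. A stage
whose producer is toggled off refuses with a message naming the producer.
Problem sizes in the default run (~3,000 nuclei, 2,000 genes, 3,000 peaks,
2,000 bulk peaks per design) were chosen as the scale at which every
recovery property is comfortably measurable on a laptop-class CPU in about
a minute.
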