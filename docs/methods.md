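# Methods

This note documents the statistical procedures implemented in `circsc`, the
assumptions behind them, the defaults that matter, and what the synthetic
data generator does and does not emulate.

## Data model and coordinates

Genomic intervals are stored 0-based half-open everywhere inside the package;
the rendered circRNA identifier (`chrom:start+1-end`) is 1-based inclusive,
and BED export is 0-based half-open, each per its format's convention.
Per-cell BSJ input is a deliberately simple 7-column TSV (`circ_id chrom
start end strand gene_id bsj_reads`) rather than any detector's native
dialect, because detector output formats drift between versions; adapters can
map onto it. Duplicate `circ_id` rows within one cell are summed only when
their coordinates agree and rejected otherwise (conservative merging); the
same id carrying different coordinates in different cells is a consistency
error rather than a silent re-keying.

## Cell QC

Per-cell metrics are library size (total gene counts), detected genes
(count > 0) and mitochondrial fraction. Outliers are defined against
`median ± nmads × 1.4826 × MAD`, with `nmads = 3` by default; 1.4826 is the
normal-consistency constant, so the rule is a robust 3-sigma cut. The default
policy flags cells low in log(library size + 1), low in log(detected
genes + 1), or high in mitochondrial fraction, and removes the union — the
standard direction of each failure mode (shallow cells, empty cells, lysed
cells). When the MAD is zero the bounds collapse onto the median and only
exact ties remain inliers; this is documented behaviour, not an error. The
mitochondrial fraction of an all-zero cell is defined as 0 to avoid 0/0; such
cells are removed by the library-size criterion anyway.

## Filtering and normalization

CircRNA filtering is dataset-level: total BSJ reads over all (QC-passing)
cells must reach 2, and 5 or more marks a circRNA high-confidence. The filter
is applied after cell QC, so sporadic detections in discarded cells cannot
rescue a circRNA.

CPM requires a per-cell denominator of "mapped reads", which count matrices
do not carry; the default proxy is gene library size plus the cell's total
BSJ reads, overridable per cell via an annotated `mapped_reads` total when
the true mapping denominator is known. Size factors are library-size factors
from the gene matrix (factor = library size / mean library size, mean exactly
1): the simplest fully testable estimator, chosen over pooled deconvolution
factors because the normalization target here is depth, not composition.
Circular-to-linear ratios with a zero host-gene denominator are reported
missing rather than infinite, since only finite ratios are interpretable
downstream. Pseudobulk aggregation is a plain per-group sum and conserves the
grand total.

## Tau and pattern classification

Tau is computed on linear-scale mean expression per group (no log
transform): with profile `x` over `n ≥ 2` groups, `T = Σ(1 − x/max(x))/(n−1)`,
0 for uniform, 1 for single-group expression, missing for an all-zero
profile. Tau is invariant to positive scaling and non-decreasing when mass is
concentrated into the maximal group; both are enforced as property tests.

Detected circRNAs are classified by detection breadth with a fixed precedence:
exactly one detecting cell → lowly expressed; all detecting cells in one cell
type → cell-type enriched; multiple types within one tissue → tissue
enriched; more than 50% of all cells → general enriched; otherwise → group
enriched. The >50% threshold and the residual definition of the group class
are package choices where only the class names and fragments of the rule are
fixed by convention; both are configurable.

## Marker detection

Markers are one-vs-rest two-sided Wilcoxon rank-sum tests per (feature, cell
type). The exact null distribution is used when the combined sample size is
at most 25 (the tie-free permutation distribution, which for complete
separation of 4 vs 4 gives p = 2/70), and the normal approximation with tie
and continuity correction otherwise; a feature with all-tied values yields
p = 1. Benjamini–Hochberg adjustment runs across all (feature, type) tests
jointly. Fold change compares the target type's mean against the best other
type's mean, both shifted by a pseudocount ε = 0.01 CPM to keep sparse
circRNA data finite; a marker requires adjusted p < 0.05 and fold ≥ 3.

## Temporal dynamics

Embryo cells map onto four ordered time points — totipotent blastomeres,
first lineage (TE/ICM), second lineage (EPI/PE), implanted embryo. Features
detected in fewer than 2 stages are dropped before clustering to damp one-off
detections. Stage mean profiles are row-standardized (mean 0, sample sd 1;
constant rows removed with a warning) and clustered with fuzzy c-means:
memberships `u_ij = 1/Σ_k (d_ij/d_ik)^(2/(m−1))`, centroids as
membership-weighted means, squared Euclidean distance. Defaults are c = 5
clusters and fuzzifier m = 1.25, in the range typically estimated for
standardized expression data (m → 1 approaches hard k-means); both are
configurable. Memberships initialize from a seeded symmetric Dirichlet(1)
draw, iteration stops when the largest centroid displacement falls below
1e-6 (or at 1000 iterations), argmax ties break to the lowest cluster index,
and a point coincident with a centroid (distance below 1e-6, which also
guards the `d^(−2/(m−1))` overflow) gets crisp membership. The objective
`Σ u^m d²` is asserted non-increasing in tests.

Cluster labeling is automated: a centroid that attains its maximum at the
first time point and ends below its start is maternal, anything else zygotic,
with a manual override accepted since trajectory labels are classically
assigned by inspection. Stage composition attributes each stage's BSJ reads
to maternal vs zygotic features; fractions sum to 1 per stage among labeled
features and a stage with zero labeled reads reports missing.

## Deconvolution

The signature matrix keeps features that are (1) detected in at least 2 cell
types and (2) a significant ≥ 3-fold marker of exactly one type — features
claimed by several types are ambiguous and dropped, making criterion (2)
checkable. Values are per-type mean CPM. A signature with fewer features than
cell types is rejected as unidentifiable.

The default solver minimizes `‖S f − b‖²` subject to `f ≥ 0` (active-set
NNLS) and renormalizes `f` to sum to 1; it is deterministic and
dependency-light. A ν-SVR mode (linear kernel, ν ∈ {0.25, 0.5, 0.75}, best by
reconstruction RMSE, negatives clipped, renormalized) is provided for
fidelity to signature-based immune deconvolution tools; it z-scores the
signature and bulk before fitting. Note that ν-SVR fits an intercept, so a
signature whose rows take only k distinct patterns over k types is
degenerate for it (the intercept absorbs one direction); NNLS has no
intercept and is unaffected, which is one reason it is the default.

Fit quality is reported as the RMSE between the standardized reconstruction
`S f` and the standardized bulk vector (population sd; a constant vector is
left unchanged by the standardization, a degenerate-case convention that only
arises for pathological reconstructions) plus the Pearson correlation on the
raw scale. Standardizing makes "lower RMSE" comparisons scale-free across
signatures with different units. Bulk profiles are intersected with the
signature by feature id, absent features imputed as zero with a warning; no
quantile normalization is applied.

## Synthetic data

Generators are pure functions of (parameters, seed), with independent
seeded substreams per matrix.

`simulate_cell_population` plants the five detection patterns directly:
lowly-expressed circRNAs get 1 + Poisson(0.5) reads in a single cell;
cell-type- and tissue-enriched circRNAs are Poisson(0.5) within their target
type or tissue; general circRNAs use a rate giving ~70% per-cell detection;
group-enriched circRNAs span two cell types in different tissues with a
6-fold higher rate in the first, making them exactly the signature-grade
features the deconvolution criteria describe (detected in ≥ 2 types,
enriched in one). BSJ counts are Poisson rather than negative binomial
because observed per-cell BSJ counts are near-binary, leaving overdispersion
unidentifiable at these rates. Gene counts are negative binomial
(dispersion 0.5) with lognormal baseline and type effects, and each circRNA's
host gene gains rate proportional to the circRNA's local activity, inducing
the host-gene/circRNA coupling the correlation analyses assume. The default
category mix (35% lowly, 20% cell-type, 10% tissue, 15% group, 20% general)
reflects a cohort dominated by sporadic detections with a substantial
housekeeping-like tail.

`simulate_embryo_time_course` draws each feature's archetype uniformly from
five shapes over the four time points — two maternal decays (sharp and slow)
and three zygotic activations peaking at successive stages — then adds
Gaussian noise (sd 0.5) to the shape, scales by depth 10, and draws Poisson
counts. The slow maternal shape decreases strictly from the first stage so
its label is unambiguous even in the noiseless limit.
`simulate_archetype_profiles` generates directly on the standardized scale
for clustering benchmarks. `simulate_bulk_mixtures` draws Dirichlet
fractions and multiplies the mixed profile by lognormal noise (sigma 0.05 on
the log scale, ≈ 5% coefficient of variation).

What the generator does **not** emulate: batch effects between studies (batch
integration is out of scope), doublets, gene-length or GC bias, dropout
beyond Poisson/NB sampling, per-cell capture-efficiency variation, and any
read-level structure. Passing recovery tests therefore demonstrate that the
estimators invert their own generative assumptions at realistic sparsity —
not that those assumptions capture every failure mode of real libraries.

## Problem sizes and numerical choices

The recovery analyses run at 5000 cells × 2000 circRNAs for classification,
1000 features × 100 cells for marker calibration, 1000 features for
clustering recovery, and 30–50 mixtures of 5 cell types for deconvolution —
sizes at which every planted effect is comfortably estimable while keeping
each analysis in seconds. Tolerances: size-factor mean within 1e-12 of 1,
membership row sums within 1e-9 of 1, centroid convergence at 1e-6,
fraction sums within 1e-9 of 1.

## Known limitations

- The pattern classifier is detection-based; with deeper sequencing, leaky
  background expression shifts features toward the broader classes.
- The marker test's exact small-sample path uses the tie-free permutation
  distribution even under ties, matching common practice but slightly
  conservative/anticonservative depending on the tie structure.
- NNLS + renormalization is not a simplex-constrained estimator; under heavy
  noise the two differ (the test oracle brute-forces the same NNLS objective).
- The fine-to-coarse cell-type aggregation map is fully configurable and
  carries no claim of matching any published reference mapping.
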