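# Methods

This note documents the models, parameter choices and numerical conventions
behind `tmepat`, and what the synthetic-data tests do and do not demonstrate.

## Study design being modeled

The pipeline targets a common design in tumor transcriptomics: unsorted
single-cell RNA-seq of tumor (and matched normal) tissue from a modest number
of patients, used to (i) catalogue microenvironmental cell clusters, (ii)
summarize each patient by the proportions of those clusters, (iii) discover
recurring composition patterns across patients, and (iv) test whether gene
signatures derived from the patterns stratify survival in large bulk cohorts.
Two patterns are modeled: N3MC (normal-like myofibroblasts, non-inflammatory
monocyte-derived macrophages, NK cells, myeloid DCs, conventional T cells)
and CP2E (cancer-associated myofibroblasts, proinflammatory monocyte-derived
macrophages, plasmacytoid DCs, exhausted CD8+ T cells), with CP2E carrying
the unfavorable prognosis.

## Quality control

Cells are kept when all of the following hold: genes detected in
[500, 10,000] (inclusive), UMIs in [1,000, 100,000] (inclusive),
mitochondrial read fraction < 0.30 (strict), hemoglobin read fraction < 0.05
(strict). The inclusive/strict split mirrors the notational convention of
printed ranges ("500–10,000") versus inequalities ("<30%"). Mitochondrial
genes are recognized by the `MT-` symbol prefix, hemoglobin genes by the
explicit list HBA1/HBA2/HBB/HBD; both sets are configurable. Removal counts
are reported per rule; a cell violating several rules counts in each, so the
per-rule sum can exceed the number removed. Filtering is idempotent.

## Normalization and highly variable genes

Counts are scaled per cell to a fixed total (default 10,000) and
log1p-transformed; zeros stay exactly zero and the matrix stays sparse. This
replaces regularized-NB variance stabilization: everything downstream
(clustering, module scores, proportions) needs only a normalized matrix and
an HVG set, and the normalizer sits behind the `preprocess` interface so an
alternative can be slotted in.

HVGs are ranked by the variance of standardized, clipped z-scores: a lowess
regression (span 0.3) of log10 variance on log10 mean gives each gene an
expected standard deviation; per-cell z-scores against that expectation are
clipped at sqrt(n_cells) so single outlier cells cannot dominate; the
variance of the clipped z-scores ranks genes (default top 3000).
Zero-variance genes rank last by construction.

## Embedding, graph, clustering, annotation

PCA runs on per-gene z-scored (clipped at ±10) HVG expression; 15 components
for the global map, 20 for compartment subsets. Component signs are fixed so
each component's score of largest absolute value is positive — this makes the
embedding deterministic and invariant to a global sign flip of the input,
which a loading-side convention would not be.

The SNN graph uses each cell's k = 20 nearest neighbors (Euclidean in PC
space, the cell itself included in its own set); edge weights are Jaccard
overlaps of neighbor sets, and edges below 1/15 are pruned. Communities come
from Louvain modularity optimization (networkx) at resolution 0.8 with a
fixed seed; k, pruning and resolution are the widely used defaults of the
single-cell toolchain this follows, exposed in `RunConfig`. On small cohorts
(a few hundred cells per patient) rare cell types can merge at resolution
0.8; the tests that need every rare type as its own cluster either use a
larger cohort or raise the resolution to 1.0.

Clusters are annotated by the reference signature (marker gene set tagged
with a compartment) of maximal mean module score; ties break by margin over
the runner-up, then lexicographically; a best score ≤ 0 yields `unassigned`.
Epithelial clusters whose tumor-tissue cell fraction is ≥ 0.9 are called
tumor — the 0.9 operationalizes "overrepresented in tumor tissue" at the
purity level such clusters typically show, and is configurable.

## Marker genes

One-vs-rest per cluster. A gene must satisfy all of: log-FC ≥ 0.25 computed
as `ln(mean(expm1(in)) + 1) − ln(mean(expm1(out)) + 1)` (the Seurat-v3
convention), expressing-cell fraction (normalized value > 0) inside ≥ 0.25,
and inside−outside fraction difference ≥ 0.25. P-values are two-sided
Wilcoxon rank-sum: exact enumeration of the rank-sum distribution over all
C(n1+n2, n1) assignments when both groups have ≤ 10 cells, otherwise the
tie-corrected normal approximation. Bonferroni adjustment is over the genes
tested per cluster and is reported, not used as a filter, since the stated
filters contain no p cutoff. Ordering is (p, −log-FC, gene name) for
determinism.

## Module scores and pathway activities

Module scores follow the expression-bin-matched control construction: genes
are cut into 24 equal-size bins by average expression; each signature gene
draws 100 control genes from its bin (signature genes excluded; with
replacement only when the bin is smaller); the pooled control list is
deduplicated; the score is mean signature expression minus mean control
expression per cell. The sampling seed is an explicit parameter so scores are
reproducible run to run. Bidirectional (up/down) sets score as
score(up) − score(down).

Pathway activity is a footprint score: per-gene z-scores across cells
(sd floor 1e-8) multiplied by a gene × pathway weight matrix restricted to
shared genes, then re-standardized per pathway. The weight matrix is external
model data supplied as TSV; the repository ships a small synthetic matrix
(`data/synthetic_pathway_weights.tsv`) for demonstration, and a published
footprint weight table drops in unchanged.

## Tumor differentiation axis

On tumor-called cells, PC1 of z-scored HVG expression defines a
differentiation axis. Orientation is anchored by the mean module score of
normal alveolar (AT1, AT2) and club cell reference programs: the sign is
chosen so PC1 correlates positively with that anchor; an anchor correlation
within 1e-6 of zero is an error demanding an explicit orientation. Per-gene
Pearson correlations with the oriented PC1 are computed for genes detected in
≥ 1% of tumor cells (constant genes get r = 0 and never enter a signature);
the top 30 by descending and ascending correlation form the alveolar/club-like
and undifferentiated signatures. Both signatures have exactly 30 genes
whenever ≥ 60 non-constant genes exist, and are disjoint by construction.

## Composition patterns

Proportions use tumor-tissue cells only: P[patient, cluster] = cells of that
cluster ÷ the patient's total cells in the cluster's compartment, over the
myeloid, lymphoid, endothelial and fibroblastic compartments. Clusters with
nonzero proportion in fewer than 3 patients are dropped; remaining columns
are not renormalized (denominators stay compartment totals). "Normalized
proportion" means per-cluster z-score across patients (sample sd); all
compartment columns concatenate into one matrix for a single PCA. The PC1
sign is fixed so the mean loading of the CP2E anchor clusters is positive,
and patients are assigned CP2E when PC1 > 0, else N3MC. Dichotomization by
PC1 sign (rather than clustering) reflects that exactly two groups ordered
along PC1 are being modeled.

The co-occurrence network computes Spearman's rho (average ranks on ties) for
every cluster pair over patients with complete values; p is an exact
permutation enumeration over all n! orderings for n ≤ 9 and the
t-approximation above; retained edges satisfy rho > 0.7 AND p < 0.05 —
positive co-occurrence only, anti-correlations are excluded by design.

Pattern gene signatures are unions of member-cluster top-10 markers with any
gene occurring in both patterns removed from both. The compact 20-gene
signature takes 10 genes per pattern by round-robin over member clusters,
each contributing its top-ranked unused marker; the round-robin rule is this
package's convention for an otherwise unspecified derivation.

## Bulk translation and survival

ssGSEA per sample: genes ranked by expression (average ranks on ties) and
walked in decreasing order; in-set genes step the running sum up by
rank^0.25 normalized by the in-set total, out-of-set genes step down by
1/(N − |S|); the enrichment score is the sum of the running difference.
With normalization on (default), all scores are divided by the global
max − min of the score matrix — note this couples a sample's normalized
score to the whole matrix, which is why the default pattern score is the
difference ES(CP2E) − ES(N3MC) rather than a ratio (normalized scores can be
≤ 0, making ratios unstable; ratio mode exists behind a flag and refuses
non-positive denominators). Samples split at the median of the score:
strictly greater is high, median and below is low.

Kaplan–Meier uses the product-limit estimator. The two-group log-rank
statistic is (ΣO − ΣE)² / ΣV with the hypergeometric variance at each
distinct event time, p from chi-square with 1 df. Cox regression is
univariate proportional hazards maximized by Newton–Raphson on the Breslow
partial likelihood (convergence |Δβ| < 1e-8, max 50 iterations), Wald CI
exp(β ± 1.96 se). A diverging β (|β| > 20) is reported as monotone
likelihood/perfect separation; Firth-type corrections are out of scope.
lifelines serves as an independent cross-check in the tests (its Efron tie
handling coincides with Breslow on tie-free fixtures), never as the
implementation.

## Ligand–receptor testing

For each ligand–receptor pair and ordered (sender, receiver) cluster pair,
the statistic is the mean of the ligand's sender-cluster mean expression and
the receptor's receiver-cluster mean; heteromeric complexes aggregate members
by minimum. A pair is tested only where the expressing-cell fraction of both
partners reaches 0.1 in their respective clusters (gate evaluated on observed
labels). The null shuffles cluster labels (default 1000 permutations;
exhaustive enumeration of all label assignments available for two clusters),
and p is the one-sided fraction of null statistics ≥ the observed.
The bundled ~40-pair table covers the Ephrin, FGF, WNT, TGFβ, BMP, JAK/STAT
and EGF families; it is a structural stand-in for a full interaction
database, which drops in via the same TSV format.

## Synthetic data: what it emulates, and what it does not

The generator plants everything downstream claims to recover. Per patient,
cell-type counts are Dirichlet-multinomial; tumor-tissue concentrations shift
2-fold up on a patient's own archetype anchors and 2-fold down on the rival's
(the study-condition contrast); normal tissue has an archetype-independent
prior. Counts are gamma-Poisson (negative binomial, dispersion 0.3 — typical
10x overdispersion) with lognormal library sizes (meanlog 9, sdlog 0.3,
≈ 8,000 UMIs). Sixteen cell-type programs across the five compartments each
carry 10 dedicated marker genes boosted e² ≈ 7.4-fold in their own cells, on
a gamma-distributed background (default 3,000 genes) plus dedicated MT- and
hemoglobin genes (≈ 8% and 0.2% of reads). Tumor cells draw a differentiation
latent u ~ Normal(0.75 or 0.25 by archetype, sd 0.15) truncated to [0, 1];
the 30 alveolar/club program genes (the AT1/AT2/club markers) scale linearly
with u and 30 dedicated undifferentiated genes with 1 − u. QC artifacts
corrupt exactly the requested fraction of cells, each violating exactly one
rule (low gene count, mito fraction ≈ 0.45, or hemoglobin fraction ≈ 0.12)
while staying inside every other bound, so filter attribution is exact.

Bulk samples are pseudobulk mixtures: archetype-specific Dirichlet
proportions times program mean-expression profiles, log2-transformed with
Gaussian noise (sd 0.3); survival is exponential with baseline hazard 0.05
and hazard multiplier exp(β) for CP2E (default β = ln 2), censoring an
independent exponential tuned to the requested rate (default 0.3).

Deliberately not modeled: doublets, batch effects, ambient RNA, realistic
gene–gene covariance within a cell type, continuous cell-state gradients
outside the tumor compartment, and patient-specific tumor programs. Passing
tests therefore demonstrate that the implementation recovers planted
structure under idealized noise — correctness of the algorithms and wiring —
not that the pipeline is robust to the full messiness of real tissue data.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 4–10 patients × 250–800 cells and
bulk cohorts of 200–500 samples, with 3–10 seeds per recovery claim and
50–100 replicates for power/calibration estimates — sizes at which every
planted effect is comfortably identifiable on a single CPU. All stochastic
stages (generator, control-gene sampling, Louvain, permutation tests) take
explicit seeds; identical seeds give identical outputs.

## Known limitations

* The Wilcoxon exact path enumerates combinations and is only used for
  groups of ≤ 10 cells; marker p-values for larger clusters rely on the
  normal approximation.
* Spearman exact p enumerates n! permutations and is capped at n ≤ 9
  patients; above that the t-approximation applies.
* Multivariate Cox (clinical covariates) is out of scope; only univariate
  hazard ratios are reported.
* ssGSEA's global-range normalization makes scores cohort-dependent;
  comparisons across cohorts should use unnormalized scores or a fixed
  reference.
* The exact ligand–receptor enumeration supports two clusters; more clusters
  fall back to sampled permutations.
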