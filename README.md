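# tmepat — tumor-microenvironment composition patterns from single-cell RNA-seq

Carcinomas differ not only in their malignant cells but in the cellular
make-up of their microenvironment, and that make-up carries prognostic
information. `tmepat` implements a pipeline for discovering patient-level
microenvironment archetypes from multi-patient single-cell RNA-seq of tumors,
and for carrying those findings into bulk expression cohorts with survival
data. It is aimed at computational biologists analyzing unsorted tumor
scRNA-seq alongside retrospective bulk cohorts.

The pipeline models two composition archetypes observed in lung
adenocarcinoma:

* **N3MC** — an inert, normal-like microenvironment: **n**ormal-like
  myofibroblasts, **n**on-inflammatory monocyte-derived macrophages,
  **N**K cells, **m**yeloid dendritic cells and **c**onventional T cells;
* **CP2E** — an immune-activated one: **c**ancer-associated myofibroblasts,
  **p**roinflammatory monocyte-derived macrophages, **p**lasmacytoid
  dendritic cells and **e**xhausted CD8+ T cells.

## What the pipeline computes

1. **QC and normalization** — cells kept with 500–10,000 genes detected,
   1,000–100,000 UMIs, mitochondrial read fraction < 30% and hemoglobin
   fraction < 5%; library-size log-normalization; highly variable genes by
   trend-standardized variance.
2. **Clustering and annotation** — PCA on z-scored HVGs, shared-nearest-
   neighbor graph (Jaccard overlap of k-NN sets, pruned at 1/15), Louvain
   communities, marker-signature annotation, and tumor-cell calling for
   epithelial clusters with ≥ 90% tumor-tissue cells.
3. **Marker genes** — one-vs-rest two-sided Wilcoxon rank-sum with Seurat-
   style filters: positive markers only, log-FC ≥ 0.25 (natural log of
   `expm1`-mean ratios), expressing-cell fraction inside ≥ 0.25, inside−outside
   fraction difference ≥ 0.25.
4. **Gene-set scores** — expression-bin-matched module scores
   (24 bins, 100 control genes per signature gene):
   `score(cell) = mean expr(signature) − mean expr(matched controls)`;
   weighted pathway-activity footprints (z-scored expression × gene-by-pathway
   weights).
5. **Tumor differentiation axis** — PC1 of tumor-cell expression, oriented so
   it correlates positively with normal alveolar/club reference scores; the
   30 genes most positively / most negatively correlated with PC1 form the
   *alveolar/club-like* and *undifferentiated* tumor-cell signatures.
6. **Composition patterns** — per-patient cluster proportions within the
   myeloid, lymphoid, endothelial and fibroblastic compartments (tumor tissue
   only; clusters present in < 3 patients excluded), z-scored and decomposed
   by PCA; patients split by the sign of the anchor-oriented PC1; Spearman
   co-occurrence network keeping edges with ρ > 0.7 and p < 0.05; pattern
   gene signatures as disjoint unions of member-cluster markers, plus a
   compact 20-gene version.
7. **Bulk translation** — single-sample GSEA (rank-weighted running sum,
   exponent α = 0.25, global-range normalization), median dichotomization of
   the CP2E − N3MC score (ties to the low group), Kaplan–Meier curves,
   log-rank test, univariate Cox proportional hazards (Breslow ties).
8. **Ligand–receptor interactions** — CellPhoneDB-style cluster-label
   permutation test on a curated pair table, with heteromeric complexes
   aggregated by member minimum.

A first-class synthetic-data module (`tmepat.synthetic`) generates
single-cell and bulk cohorts with complete ground truth — planted archetypes,
marker programs, a continuous tumor differentiation latent, QC-failing cells
and survival with a planted hazard contrast — so every stage can be tested
against what was planted.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort (10 patients, 5 per archetype, 500 cells each) and write their tables
under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py      # kept 4500 / 5000 cells;
                                           # removed set == planted artifacts
python analysis/03_cluster_annotate.py     # 15 clusters, ARI 0.99 vs truth
python analysis/06_tme_patterns.py
python analysis/07_bulk_survival.py
```

`06_tme_patterns.py` prints the per-patient pattern assignment, e.g.

```
         pattern_pc1 group
patient
P001          -3.034  N3MC
P002           3.198  CP2E
...
accuracy vs planted archetypes: 100%
7 co-occurrence edges retained (rho > 0.7, p < 0.05)
```

meaning every patient lands on its planted archetype and only strongly
co-occurring cluster pairs survive the network thresholds. `07_bulk_survival.py`
scores a 200-sample pseudobulk cohort with a planted 2× hazard for CP2E:

```
log-rank chi2 = 21.83, p = 2.98e-06
Cox HR (high vs low CP2E-minus-N3MC score) = 2.25 [1.59, 3.19], p = 5.04e-06
planted hazard ratio: 2.00
```

the estimated hazard ratio bracketing the planted 2.0: samples with a high
CP2E-minus-N3MC enrichment score die about twice as fast.

## Layout

```
src/tmepat/        library: core_io, synthetic, preprocess, cluster, scoring,
                   markers, tumor_axis, patterns, survival, interactions, pipeline
analysis/          numbered narrative drivers (simulate → QC → ... → survival)
tests/             pytest suite incl. end-to-end acceptance properties
scripts/           acceptance.py
docs/methods.md    model and design notes
```
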