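"""End-to-end convenience drivers chaining the pipeline stages.

These functions wire the module-level operations together in the order the
analysis runs them: QC -> normalization -> HVG -> PCA -> SNN -> Louvain ->
annotation -> tumor calling -> composition -> pattern PCA. They exist so the
analysis scripts, the tests and the acceptance checks all execute the same
code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import (
    ClusterAssignment,
    annotate_clusters,
    build_snn,
    call_tumor_clusters,
    cluster_graph,
    pca_embed,
)
from .core_io import CountMatrix, GeneSignature, NormMatrix, RunConfig
from .patterns import (
    CompositionTable,
    PatternAssignment,
    compute_proportions,
    filter_rare_clusters,
    pattern_pca,
)
from .preprocess import QCReport, QCThresholds, normalize_log, qc_filter, select_hvg
from .scoring import ModuleScoreParams
from .synthetic import CP2E_ANCHORS, N3MC_ANCHORS

__all__ = ["PipelineResult", "cluster_cells", "recover_patterns"]


@dataclass
class PipelineResult:
    nm: NormMatrix
    meta: pd.DataFrame
    assignment: ClusterAssignment
    qc_report: QCReport
    composition: CompositionTable | None = None
    pattern: PatternAssignment | None = None


def cluster_cells(
    counts: CountMatrix,
    meta: pd.DataFrame,
    references: list[GeneSignature],
    config: RunConfig | None = None,
) -> PipelineResult:
    """QC, normalize, embed, cluster, annotate, and call tumor clusters."""
    cfg = config or RunConfig()
    thresholds = QCThresholds(
        min_genes=cfg.min_genes, max_genes=cfg.max_genes,
        min_umi=cfg.min_umi, max_umi=cfg.max_umi,
        max_mito_frac=cfg.max_mito_frac, max_hb_frac=cfg.max_hb_frac,
    )
    counts_f, meta_f, report = qc_filter(counts, meta, thresholds)
    nm = normalize_log(counts_f, scale=cfg.norm_scale)
    hvg = select_hvg(nm, cfg.n_hvg)
    pcs = pca_embed(nm, hvg, n_pcs=cfg.n_pcs_global)
    g = build_snn(pcs, k=cfg.snn_k, prune=cfg.snn_prune)
    ca = cluster_graph(g, resolution=cfg.resolution, seed=cfg.seed, cells=nm.cells)
    ca = annotate_clusters(ca, nm, references,
                           ModuleScoreParams(cfg.n_bins, cfg.n_ctrl, cfg.seed))
    ca = call_tumor_clusters(ca, meta_f, min_tumor_frac=cfg.min_tumor_frac)
    return PipelineResult(nm=nm, meta=meta_f, assignment=ca, qc_report=report)


def recover_patterns(
    counts: CountMatrix,
    meta: pd.DataFrame,
    references: list[GeneSignature],
    config: RunConfig | None = None,
    anchors: dict[str, list[str]] | None = None,
) -> PipelineResult:
    """Full chain through composition analysis and pattern assignment."""
    cfg = config or RunConfig()
    res = cluster_cells(counts, meta, references, cfg)
    ct = compute_proportions(res.assignment, res.meta)
    ct = filter_rare_clusters(ct, min_patients=cfg.min_pattern_patients)
    anchors = anchors or {"N3MC": list(N3MC_ANCHORS), "CP2E": list(CP2E_ANCHORS)}
    anchors = {
        k: [a for a in v if a in ct.P.columns] for k, v in anchors.items()
    }
    res.composition = ct
    res.pattern = pattern_pca(ct, anchors)
    return res
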