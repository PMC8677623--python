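"""Quality-control filtering, log-normalization and highly-variable-gene selection.

QC keeps cells with 500-10,000 genes detected and 1,000-100,000 UMIs (both
ranges inclusive), mitochondrial read fraction < 30% and hemoglobin read
fraction < 5% (both strict). Normalization is library-size scaling to a fixed
total followed by log1p; HVGs are ranked by the variance of trend-standardized,
clipped z-scores (local regression of log variance on log mean).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix, NormMatrix
from .synthetic import HEMOGLOBIN_GENES

logger = logging.getLogger("tmepat")

__all__ = ["QCThresholds", "QCReport", "qc_filter", "normalize_log", "select_hvg"]


@dataclass
class QCThresholds:
    min_genes: int = 500
    max_genes: int = 10_000
    min_umi: int = 1_000
    max_umi: int = 100_000
    max_mito_frac: float = 0.30
    max_hb_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes or self.min_umi > self.max_umi:
            raise ValueError("min bound exceeds max bound")
        for frac in (self.max_mito_frac, self.max_hb_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction thresholds must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts. Cells violating several rules count in each,
    so the per-rule sum can exceed the number of removed cells."""

    n_input: int
    n_kept: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.removed_by_rule), "cells_removed": list(self.removed_by_rule.values())}
        )


def qc_filter(
    m: CountMatrix,
    meta: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "MT-",
    hb_genes: list[str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame | None, QCReport]:
    """Remove low-quality cells; count bounds inclusive, fraction bounds strict."""
    t = thresholds or QCThresholds()
    hb_genes = hb_genes if hb_genes is not None else list(HEMOGLOBIN_GENES)

    counts = m.counts.tocsc()
    genes_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    umi = np.asarray(counts.sum(axis=0)).ravel().astype(float)

    mito_rows = np.array([g.startswith(mito_prefix) for g in m.genes])
    hb_rows = np.isin(np.asarray(m.genes, dtype=object), hb_genes)
    if not mito_rows.any():
        warnings.warn("no mitochondrial genes found; mito-fraction rule is inert")
    if not hb_rows.any():
        warnings.warn("no hemoglobin genes found; hb-fraction rule is inert")

    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, np.asarray(counts[mito_rows].sum(axis=0)).ravel() / umi, 0.0)
        hb_frac = np.where(umi > 0, np.asarray(counts[hb_rows].sum(axis=0)).ravel() / umi, 0.0)

    fails = {
        "min_genes": genes_detected < t.min_genes,
        "max_genes": genes_detected > t.max_genes,
        "min_umi": umi < t.min_umi,
        "max_umi": umi > t.max_umi,
        "mito_frac": mito_frac >= t.max_mito_frac,
        "hb_frac": hb_frac >= t.max_hb_frac,
    }
    keep = ~np.any(list(fails.values()), axis=0)

    report = QCReport(
        n_input=len(m.cells),
        n_kept=int(keep.sum()),
        removed_by_rule={rule: int(mask.sum()) for rule, mask in fails.items()},
    )
    if not keep.any():
        dominant = max(report.removed_by_rule, key=report.removed_by_rule.get)
        raise ValueError(f"QC removed every cell; dominant failing rule: {dominant}")

    out = m.subset_cells(keep)
    out_meta = meta.loc[out.cells] if meta is not None else None
    logger.info("qc_filter: kept %d / %d cells", report.n_kept, report.n_input)
    return out, out_meta, report


def normalize_log(m: CountMatrix, scale: float = 1e4) -> NormMatrix:
    """Per-cell library-size normalization to *scale* counts, then ln(1 + x).

    Sparse zeros are preserved; requires no all-zero cells (guaranteed post-QC).
    """
    counts = m.counts.tocsc().astype(np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("all-zero cells present; run qc_filter first")
    counts = counts.multiply(sp.csr_matrix(scale / totals))  # scale each column
    counts = counts.tocsr()
    counts.data = np.log1p(counts.data)
    return NormMatrix(genes=list(m.genes), cells=list(m.cells), X=counts)


def _trend_fit(log_mean: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Local regression of log variance on log mean (lowess)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(log_var, log_mean, frac=0.3, return_sorted=False)
    return fitted


def select_hvg(nm: NormMatrix, n: int = 3000, clip: float | None = None) -> list[int]:
    """Indices of the *n* genes with highest trend-standardized variance.

    Per-gene z-scores use the lowess-expected standard deviation and are
    clipped at ``sqrt(n_cells)`` before the ranking variance is computed, so
    single outlier cells cannot dominate. Deterministic given the input; ties
    broken by gene order.
    """
    n_genes, n_cells = nm.shape
    if n > n_genes:
        warnings.warn(f"requested {n} HVGs but only {n_genes} genes; returning all")
        n = n_genes
    X = nm.X.tocsr()
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)

    std_var = np.zeros(n_genes)
    positive = var > 1e-12
    if positive.sum() >= 2:
        log_mean = np.log10(np.clip(mean[positive], 1e-12, None))
        log_var = np.log10(var[positive])
        expected_sd = np.sqrt(10.0 ** _trend_fit(log_mean, log_var))
        expected_sd = np.clip(expected_sd, 1e-8, None)
        clip_val = clip if clip is not None else np.sqrt(n_cells)

        # variance of clipped z-scores, computed sparsely:
        # zeros contribute z0 = (0 - mu) / sd at multiplicity (n_cells - nnz)
        pos_idx = np.flatnonzero(positive)
        sub = X[pos_idx]
        mu = mean[pos_idx]
        sd = expected_sd
        z0 = np.clip(-mu / sd, -clip_val, clip_val)
        sum_z = np.zeros(len(pos_idx))
        sum_z2 = np.zeros(len(pos_idx))
        indptr = sub.indptr
        data = sub.data
        for i in range(len(pos_idx)):
            z = np.clip((data[indptr[i]:indptr[i + 1]] - mu[i]) / sd[i], -clip_val, clip_val)
            nz = n_cells - len(z)
            s1 = z.sum() + nz * z0[i]
            s2 = (z**2).sum() + nz * z0[i] ** 2
            sum_z[i] = s1
            sum_z2[i] = s2
        std_var[pos_idx] = (sum_z2 - sum_z**2 / n_cells) / max(n_cells - 1, 1)

    order = np.lexsort((np.arange(n_genes), -std_var))
    return sorted(order[:n].tolist())
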