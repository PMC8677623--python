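"""Tumor-cell differentiation axis and the paired 30-gene signatures.

PC1 of tumor-cell expression captures a differentiation gradient. The axis is
oriented so it correlates positively with reference module scores of normal
alveolar/club cell programs; the 30 genes most positively and most negatively
correlated with the oriented axis become the "alveolar/club-like" and
"undifferentiated" tumor-cell signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSignature, NormMatrix
from .cluster import pca_embed
from .preprocess import select_hvg
from .scoring import ModuleScoreParams, module_score

__all__ = ["DifferentiationAxis", "derive_axis", "score_axis_signatures"]


@dataclass
class DifferentiationAxis:
    pc1_scores: pd.Series  # per tumor cell
    gene_corr: pd.Series  # per eligible gene, Pearson r with pc1
    sig_alveolar: GeneSignature
    sig_undiff: GeneSignature
    orientation: str = "alveolar-positive"


def _pearson_with_vector(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X with v; rows of zero variance get r = 0."""
    vc = v - v.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    num = Xc @ vc
    den = np.sqrt((Xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def derive_axis(
    nm: NormMatrix,
    ref_scores: pd.DataFrame | np.ndarray,
    n_sig: int = 30,
    n_hvg: int = 2000,
    n_pcs: int = 20,
    min_detect_frac: float = 0.01,
) -> DifferentiationAxis:
    """Derive the differentiation axis from tumor-cell expression.

    *nm* must be restricted to tumor epithelial cells; *ref_scores* holds
    per-cell module scores of the normal alveolar/club reference programs
    (columns averaged to a single orientation anchor).

    Gene-axis correlations are computed for genes detected in at least
    ``min_detect_frac`` of cells; each signature takes the top ``n_sig`` genes
    per direction (fewer, with a warning, only if the universe is smaller).
    """
    n_genes, n_cells = nm.shape
    if n_cells < 50:
        raise ValueError(f"need >= 50 tumor cells, got {n_cells}")
    ref = np.asarray(ref_scores, dtype=float)
    if ref.ndim == 2:
        ref = ref.mean(axis=1)
    if len(ref) != n_cells:
        raise ValueError("ref_scores length does not match cell count")

    hvg = select_hvg(nm, min(n_hvg, n_genes))
    pcs = pca_embed(nm, hvg, n_pcs=min(n_pcs, n_cells - 1, len(hvg)))
    pc1 = pcs[:, 0]

    anchor_r = float(np.corrcoef(pc1, ref)[0, 1])
    if abs(anchor_r) < 1e-6 or not np.isfinite(anchor_r):
        raise ValueError(
            "orientation anchor correlation is ~0; supply an explicit orientation"
        )
    if anchor_r < 0:
        pc1 = -pc1

    detect_frac = np.asarray((nm.X > 0).sum(axis=1)).ravel() / n_cells
    eligible = np.flatnonzero(detect_frac >= min_detect_frac)
    X = np.asarray(nm.X[eligible].todense(), dtype=float)
    r = _pearson_with_vector(X, pc1)
    nonconstant = X.std(axis=1) > 0
    r = np.where(nonconstant, r, 0.0)

    gene_names = np.asarray(nm.genes, dtype=object)[eligible]
    # constant genes never enter either signature
    order = np.lexsort((gene_names, -r))
    cand = [i for i in order if nonconstant[i]]
    n_half = min(n_sig, len(cand) // 2)
    if n_half < n_sig:
        warnings.warn(f"only {len(cand)} non-constant genes; signatures have {n_half} genes")
    top_pos = cand[:n_half]
    top_neg = cand[-n_half:][::-1]

    return DifferentiationAxis(
        pc1_scores=pd.Series(pc1, index=nm.cells, name="pc1"),
        gene_corr=pd.Series(r, index=gene_names, name="pearson_r"),
        sig_alveolar=GeneSignature(
            name="alveolar_club_like", genes=[str(gene_names[i]) for i in top_pos],
            direction="bidirectional-positive",
        ),
        sig_undiff=GeneSignature(
            name="undifferentiated", genes=[str(gene_names[i]) for i in top_neg],
            direction="bidirectional-negative",
        ),
    )


def score_axis_signatures(
    nm: NormMatrix,
    axis: DifferentiationAxis,
    params: ModuleScoreParams | None = None,
    patients: pd.Series | None = None,
) -> pd.DataFrame:
    """Module scores of both axis signatures per cell (and per patient)."""
    scores = pd.DataFrame(
        {
            axis.sig_alveolar.name: module_score(nm, axis.sig_alveolar, params),
            axis.sig_undiff.name: module_score(nm, axis.sig_undiff, params),
        },
        index=nm.cells,
    )
    if patients is not None:
        return scores.groupby(patients.reindex(scores.index)).mean()
    return scores
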