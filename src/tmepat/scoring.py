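"""Per-cell gene-set scores.

``module_score`` implements the expression-bin-matched control score: genes
are binned by average expression, each signature gene draws control genes from
its own bin, and the score is the mean signature expression minus the mean
control expression. ``pathway_activity`` is a weighted footprint score
(z-scored expression times a gene x pathway weight matrix, re-standardized).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSignature, NormMatrix

logger = logging.getLogger("tmepat")

__all__ = [
    "ModuleScoreParams",
    "PathwayWeights",
    "module_score",
    "bidirectional_score",
    "pathway_activity",
    "group_mean_scores",
]


@dataclass
class ModuleScoreParams:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")


@dataclass
class PathwayWeights:
    """Gene x pathway weight matrix for footprint-style pathway scoring."""

    genes: list[str]
    pathways: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.genes), len(self.pathways)):
            raise ValueError("W shape must be genes x pathways")
        if not np.isfinite(self.W).all():
            raise ValueError("weights must be finite")

    @classmethod
    def from_tsv(cls, path) -> "PathwayWeights":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(genes=df.index.tolist(), pathways=df.columns.tolist(), W=df.values)


def _expression_bins(avg: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size bins of genes by average expression (rank-based cut)."""
    n = len(avg)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def module_score(
    nm: NormMatrix,
    sig: GeneSignature,
    params: ModuleScoreParams | None = None,
) -> np.ndarray:
    """Expression-bin-matched module score per cell.

    For each signature gene, ``n_ctrl`` control genes are sampled from the
    gene's expression bin (signature genes excluded; with replacement when the
    bin is smaller than ``n_ctrl``). The pooled control list is deduplicated
    before averaging. Deterministic given ``params.seed``.
    """
    p = params or ModuleScoreParams()
    lut = {g: i for i, g in enumerate(nm.genes)}
    sig_idx = [lut[g] for g in sig.genes if g in lut]
    missing = [g for g in sig.genes if g not in lut]
    if missing:
        warnings.warn(f"signature {sig.name!r}: {len(missing)} gene(s) absent, dropped")
    if not sig_idx:
        raise ValueError(f"signature {sig.name!r} has no genes in the matrix")

    X = nm.X.tocsr()
    avg = np.asarray(X.mean(axis=1)).ravel()
    bins = _expression_bins(avg, p.n_bins)

    rng = np.random.default_rng(p.seed)
    sig_set = set(sig_idx)
    bin_pools = {
        b: np.array([i for i in np.flatnonzero(bins == b) if i not in sig_set])
        for b in np.unique(bins[sig_idx])
    }
    ctrl: list[int] = []
    for gi in sig_idx:
        pool = bin_pools[bins[gi]]
        if len(pool) == 0:
            warnings.warn(f"signature {sig.name!r}: empty control bin for a gene; skipped")
            continue
        replace = len(pool) < p.n_ctrl
        ctrl.extend(rng.choice(pool, size=p.n_ctrl, replace=replace).tolist())
    ctrl_idx = sorted(set(ctrl))
    if not ctrl_idx:
        raise ValueError(f"signature {sig.name!r}: no control genes available")

    sig_mean = np.asarray(X[sorted(sig_set)].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[ctrl_idx].mean(axis=0)).ravel()
    return sig_mean - ctrl_mean


def bidirectional_score(
    nm: NormMatrix,
    up: GeneSignature,
    down: GeneSignature,
    params: ModuleScoreParams | None = None,
) -> np.ndarray:
    """score(up) - score(down), for paired up/down-regulated gene sets."""
    return module_score(nm, up, params) - module_score(nm, down, params)


def pathway_activity(nm: NormMatrix, pw: PathwayWeights) -> pd.DataFrame:
    """Cell x pathway activity: per-gene z-scores times the weight matrix,
    then per-pathway standardization across cells."""
    lut = {g: i for i, g in enumerate(nm.genes)}
    shared = [(lut[g], j) for j, g in enumerate(pw.genes) if g in lut]
    if not shared:
        raise ValueError("no weighted genes present in the matrix")
    gidx = np.array([i for i, _ in shared])
    widx = np.array([j for _, j in shared])

    X = np.asarray(nm.X[gidx].todense(), dtype=float)  # shared genes x cells
    mu = X.mean(axis=1, keepdims=True)
    sd = np.clip(X.std(axis=1, ddof=0, keepdims=True), 1e-8, None)
    Z = (X - mu) / sd

    keep = []
    for k, name in enumerate(pw.pathways):
        if np.any(pw.W[widx, k] != 0):
            keep.append(k)
        else:
            warnings.warn(f"pathway {name!r} has no nonzero weights on shared genes; dropped")
    if not keep:
        raise ValueError("no pathway has weighted genes in the matrix")

    scores = Z.T @ pw.W[np.ix_(widx, keep)]  # cells x kept pathways
    mu_s = scores.mean(axis=0, keepdims=True)
    sd_s = np.clip(scores.std(axis=0, ddof=0, keepdims=True), 1e-8, None)
    scores = (scores - mu_s) / sd_s
    return pd.DataFrame(scores, index=nm.cells, columns=[pw.pathways[k] for k in keep])


def group_mean_scores(scores: pd.Series | pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Arithmetic mean of per-cell scores within groups, with group sizes.

    Empty groups are simply absent from the result.
    """
    df = scores.to_frame("score") if isinstance(scores, pd.Series) else scores.copy()
    if not groups.index.equals(df.index):
        groups = groups.reindex(df.index)
        if groups.isna().any():
            raise ValueError("group labels do not cover all scored cells")
    out = df.groupby(groups, observed=True).mean()
    out["n"] = df.groupby(groups, observed=True).size()
    return out
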