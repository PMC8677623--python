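"""Cluster marker-gene detection: one-vs-rest Wilcoxon with fraction filters.

A gene is a marker of a cluster only if it is a *positive* marker with
log fold change >= 0.25 (natural log of expm1-mean ratios, pseudocount 1),
is expressed in >= 25% of in-cluster cells, and the expressing-cell fraction
differs by >= 0.25 between inside and outside. P-values come from the
two-sided Wilcoxon rank-sum test (exact rank-sum enumeration when both groups
have <= 10 cells, tie-corrected normal approximation otherwise) and are
Bonferroni-adjusted over the genes tested per cluster; the adjusted p is
reported, not used as a filter.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSignature, NormMatrix
from .cluster import ClusterAssignment

logger = logging.getLogger("tmepat")

__all__ = ["find_markers", "top_markers", "wilcoxon_rank_sum"]

EXACT_MAX_N = 10


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n1+n2, n1) group assignments.

    p = P(|W - E[W]| >= |W_obs - E[W]|) over the permutation distribution of
    the rank sum W of the first group (ties handled by average ranks).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    d_obs = abs(w_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 10 observations, otherwise the
    tie-corrected normal approximation.
    """
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue)


def _log_fc(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    """ln(mean(expm1(in)) + 1) - ln(mean(expm1(out)) + 1)."""
    return np.log(mean_in + 1.0) - np.log(mean_out + 1.0)


def find_markers(
    nm: NormMatrix,
    ca: ClusterAssignment,
    logfc_min: float = 0.25,
    min_pct: float = 0.25,
    min_diff_pct: float = 0.25,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest positive markers per cluster.

    Returns a DataFrame with columns gene, cluster, log_fc, pct_in, pct_out,
    p_value, p_adj, sorted within cluster by (p, -log_fc, gene).
    """
    labels = np.asarray(ca.labels)
    cluster_ids = np.unique(labels)
    if len(cluster_ids) < 2:
        raise ValueError("need at least 2 clusters")

    X = nm.X.tocsr()
    expm1 = X.copy()
    expm1.data = np.expm1(expm1.data)
    n_cells = X.shape[1]
    genes = np.asarray(nm.genes, dtype=object)

    rows = []
    for cid in cluster_ids:
        in_mask = labels == cid
        n_in = int(in_mask.sum())
        n_out = n_cells - n_in
        if n_in < min_cluster_size:
            warnings.warn(f"cluster {cid} has {n_in} cells (< {min_cluster_size}); skipped")
            continue
        in_idx = np.flatnonzero(in_mask)
        out_idx = np.flatnonzero(~in_mask)

        pct_in = np.asarray((X[:, in_idx] > 0).sum(axis=1)).ravel() / n_in
        pct_out = np.asarray((X[:, out_idx] > 0).sum(axis=1)).ravel() / n_out
        mean_in = np.asarray(expm1[:, in_idx].mean(axis=1)).ravel()
        mean_out = np.asarray(expm1[:, out_idx].mean(axis=1)).ravel()
        log_fc = _log_fc(mean_in, mean_out)

        passing = np.flatnonzero(
            (log_fc >= logfc_min) & (pct_in >= min_pct) & (pct_in - pct_out >= min_diff_pct)
        )
        if passing.size == 0:
            continue
        sub = np.asarray(X[passing].todense())
        for g_local, g in enumerate(passing):
            p = wilcoxon_rank_sum(sub[g_local, in_idx], sub[g_local, out_idx])
            rows.append({
                "gene": genes[g], "cluster": cid, "log_fc": float(log_fc[g]),
                "pct_in": float(pct_in[g]), "pct_out": float(pct_out[g]),
                "p_value": p, "p_adj": min(1.0, p * passing.size),
            })

    if not rows:
        return pd.DataFrame(
            columns=["gene", "cluster", "log_fc", "pct_in", "pct_out", "p_value", "p_adj"]
        )
    df = pd.DataFrame(rows)
    df["_neg_lfc"] = -df["log_fc"]
    df = (
        df.sort_values(["cluster", "p_value", "_neg_lfc", "gene"], kind="stable")
        .drop(columns="_neg_lfc")
        .reset_index(drop=True)
    )
    return df


def top_markers(markers: pd.DataFrame, n: int = 10,
                label_by: pd.Series | None = None) -> dict[str, GeneSignature]:
    """First *n* retained markers per cluster as GeneSignatures.

    ``label_by`` optionally maps cluster ids to names (e.g. annotated cell
    types); clusters sharing a name pool their markers in rank order.
    """
    out: dict[str, GeneSignature] = {}
    collected: dict[str, list[str]] = {}
    for cid, sub in markers.groupby("cluster", sort=True):
        name = str(label_by.loc[cid]) if label_by is not None else str(cid)
        collected.setdefault(name, [])
        for g in sub["gene"]:
            if g not in collected[name]:
                collected[name].append(g)
    for name, gene_list in collected.items():
        if len(gene_list) < n:
            logger.info("top_markers: cluster %s has only %d markers (< %d)",
                        name, len(gene_list), n)
        out[name] = GeneSignature(name=name, genes=gene_list[:n], direction="up")
    return out
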