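"""Ligand-receptor interaction testing between cell clusters.

For each ligand-receptor pair and ordered (sender, receiver) cluster pair, the
statistic is the mean of the ligand's sender-cluster mean and the receptor's
receiver-cluster mean; a pair is only tested where both partners are expressed
in at least ``expr_frac`` of the relevant cluster's cells. Significance comes
from a cluster-label permutation null (one-sided: fraction of permuted
statistics >= observed). Heteromeric complexes aggregate members by minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import NormMatrix
from .cluster import ClusterAssignment

logger = logging.getLogger("tmepat")

__all__ = ["LRPair", "load_lr_pairs", "default_lr_pairs", "lr_test", "count_interactions"]


@dataclass
class LRPair:
    """Ligand and receptor (each possibly a complex) with a family tag."""

    ligand: list[str]
    receptor: list[str]
    family: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("both partners must be non-empty")

    @property
    def name(self) -> str:
        return "+".join(self.ligand) + "->" + "+".join(self.receptor)


def load_lr_pairs(path: str | Path) -> list[LRPair]:
    """Parse a (ligand, receptor, family) TSV; complex members joined by '+'."""
    df = pd.read_csv(path, sep="\t")
    return [
        LRPair(
            ligand=str(r["ligand"]).split("+"),
            receptor=str(r["receptor"]).split("+"),
            family=str(r.get("family", "")),
        )
        for _, r in df.iterrows()
    ]


def default_lr_pairs() -> list[LRPair]:
    """The curated in-package pair table (major paracrine families)."""
    with resources.as_file(resources.files("tmepat") / "data" / "lr_pairs.tsv") as p:
        return load_lr_pairs(p)


def _cluster_stats(X: np.ndarray, labels: np.ndarray, ids: np.ndarray):
    """Per-cluster mean and expressing-cell fraction; X is genes x cells dense."""
    means = np.empty((X.shape[0], len(ids)))
    fracs = np.empty((X.shape[0], len(ids)))
    for k, cid in enumerate(ids):
        cols = labels == cid
        means[:, k] = X[:, cols].mean(axis=1)
        fracs[:, k] = (X[:, cols] > 0).mean(axis=1)
    return means, fracs


def lr_test(
    nm: NormMatrix,
    ca: ClusterAssignment,
    pairs: Sequence[LRPair] | None = None,
    n_perm: int = 1000,
    expr_frac: float = 0.1,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """Permutation test of ligand-receptor interactions between cluster pairs.

    Returns one row per (pair, sender, receiver) tested, with mean_score, p
    and a significance flag at p < 0.05. With ``exact=True`` (two clusters
    only) the null enumerates every distinct label assignment instead of
    sampling, so p-values are exact.
    """
    pairs = list(pairs) if pairs is not None else default_lr_pairs()
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} gives coarse p-value granularity")
    labels = np.asarray(ca.labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")

    lut = {g: i for i, g in enumerate(nm.genes)}
    used: list[LRPair] = []
    gene_rows: list[int] = []
    for pr in pairs:
        if all(g in lut for g in pr.ligand + pr.receptor):
            used.append(pr)
            gene_rows.extend(lut[g] for g in pr.ligand + pr.receptor)
        else:
            logger.info("lr_test: pair %s unresolvable; dropped", pr.name)
    if not used:
        return pd.DataFrame(
            columns=["pair", "family", "sender", "receiver", "mean_score", "p", "significant"]
        )

    rows_idx = sorted(set(gene_rows))
    row_of = {r: i for i, r in enumerate(rows_idx)}
    X = np.asarray(nm.X[rows_idx].todense(), dtype=float)

    def complex_stats(members: list[str], means: np.ndarray, fracs: np.ndarray):
        sel = [row_of[lut[g]] for g in members]
        return means[sel].min(axis=0), fracs[sel].min(axis=0)

    means, fracs = _cluster_stats(X, labels, ids)

    # which (pair, sender, receiver) combinations are tested
    tested = []
    for pr in used:
        lmean, lfrac = complex_stats(pr.ligand, means, fracs)
        rmean, rfrac = complex_stats(pr.receptor, means, fracs)
        for si, s in enumerate(ids):
            if lfrac[si] < expr_frac:
                continue
            for ri, r in enumerate(ids):
                if si == ri or rfrac[ri] < expr_frac:
                    continue
                tested.append((pr, s, r, 0.5 * (lmean[si] + rmean[ri])))
    if not tested:
        return pd.DataFrame(
            columns=["pair", "family", "sender", "receiver", "mean_score", "p", "significant"]
        )

    # permutation null on cluster means only (fractions are part of the
    # expression gate, evaluated on the observed labels, as in the reference
    # statistic)
    id_of = {c: k for k, c in enumerate(ids)}
    exceed = np.zeros(len(tested))
    if exact:
        if len(ids) != 2:
            raise ValueError("exact enumeration supports exactly 2 clusters")
        n1 = int((labels == ids[0]).sum())
        n_total = comb(len(labels), n1)
        count = 0
        for pos in combinations(range(len(labels)), n1):
            perm_labels = np.full(len(labels), ids[1])
            perm_labels[list(pos)] = ids[0]
            pm, _ = _cluster_stats(X, perm_labels, ids)
            for j, (pr, s, r, obs) in enumerate(tested):
                lm, _ = complex_stats(pr.ligand, pm, pm)
                rm, _ = complex_stats(pr.receptor, pm, pm)
                stat = 0.5 * (lm[id_of[s]] + rm[id_of[r]])
                if stat >= obs - 1e-12:
                    exceed[j] += 1
            count += 1
        denom = n_total
        assert count == n_total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm_labels = rng.permutation(labels)
            pm, _ = _cluster_stats(X, perm_labels, ids)
            for j, (pr, s, r, obs) in enumerate(tested):
                lm, _ = complex_stats(pr.ligand, pm, pm)
                rm, _ = complex_stats(pr.receptor, pm, pm)
                stat = 0.5 * (lm[id_of[s]] + rm[id_of[r]])
                if stat >= obs - 1e-12:
                    exceed[j] += 1
        denom = n_perm

    rows = []
    for j, (pr, s, r, obs) in enumerate(tested):
        p = exceed[j] / denom
        rows.append({
            "pair": pr.name, "family": pr.family, "sender": s, "receiver": r,
            "mean_score": obs, "p": p, "significant": p < 0.05,
        })
    return pd.DataFrame(rows)


def count_interactions(
    results: pd.DataFrame,
    senders: Sequence | None = None,
    receivers: Sequence | None = None,
) -> pd.DataFrame:
    """Count significant interactions per (sender, receiver, family)."""
    cols = ["sender", "receiver", "family", "n_significant"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    df = results
    if senders is not None:
        df = df[df["sender"].isin(list(senders))]
    if receivers is not None:
        df = df[df["receiver"].isin(list(receivers))]
    sig = df[df["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    out = (
        sig.groupby(["sender", "receiver", "family"], observed=True)
        .size()
        .rename("n_significant")
        .reset_index()
    )
    return out
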