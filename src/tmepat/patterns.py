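"""Microenvironment composition patterns across patients.

Per-patient cell-cluster proportions within the stromal/immune compartments
are z-scored and decomposed by PCA; the first component separates the two
composition archetypes (N3MC vs CP2E), oriented by anchor clusters. A
Spearman correlation network links co-occurring clusters, and pattern-level
gene signatures are assembled from member-cluster markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSignature
from .cluster import ClusterAssignment

__all__ = [
    "CompositionTable",
    "PatternAssignment",
    "compute_proportions",
    "filter_rare_clusters",
    "pattern_pca",
    "correlation_network",
    "assemble_pattern_signatures",
    "reduce_signature",
    "spearman_exact_p",
]

DEFAULT_COMPARTMENTS = ["myeloid", "lymphoid", "endothelial", "fibroblastic"]


@dataclass
class CompositionTable:
    """Patient x cluster proportion matrix (within-compartment denominators)."""

    P: pd.DataFrame  # proportions
    compartments: pd.Series  # cluster -> compartment
    Z: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.Z.empty:
            sd = self.P.std(axis=0, ddof=1)
            z = (self.P - self.P.mean(axis=0)) / sd.replace(0.0, np.nan)
            self.Z = z.fillna(0.0)


@dataclass
class PatternAssignment:
    pattern_pc1: pd.Series  # per patient
    group: pd.Series  # per patient: N3MC or CP2E
    loadings: pd.Series  # per cluster
    anchor_clusters: dict[str, list[str]]


def compute_proportions(
    ca: ClusterAssignment,
    meta: pd.DataFrame,
    compartments: Sequence[str] = DEFAULT_COMPARTMENTS,
    column: str = "cell_type",
) -> CompositionTable:
    """Per-patient proportions of cell clusters within each compartment.

    Only tumor-tissue cells enter (pattern discovery concerns the tumor
    microenvironment). The denominator is the patient's total cell count in
    the cluster's compartment, so proportions sum to 1 per compartment.
    Patients lacking a compartment entirely get missing values with a warning.
    """
    df = ca.to_frame().join(meta.loc[ca.cells, ["patient", "tissue"]])
    df = df[(df["tissue"] == "tumor") & df["compartment"].isin(compartments)]
    if df.empty:
        raise ValueError("no tumor-tissue cells in the requested compartments")

    counts = df.groupby(["patient", column], observed=True).size().unstack(fill_value=0)
    comp_of = (
        df.drop_duplicates(column).set_index(column)["compartment"].reindex(counts.columns)
    )
    P = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for comp in comp_of.unique():
        cols = comp_of.index[comp_of == comp]
        totals = counts[cols].sum(axis=1)
        empty = totals == 0
        if empty.any():
            warnings.warn(
                f"patients {list(counts.index[empty])} have no {comp} cells; "
                "proportions set missing"
            )
        P[cols] = counts[cols].div(totals.replace(0, np.nan), axis=0)
    return CompositionTable(P=P, compartments=comp_of)


def filter_rare_clusters(ct: CompositionTable, min_patients: int = 3) -> CompositionTable:
    """Drop clusters with nonzero proportion in fewer than *min_patients*
    patients. Remaining proportions keep their compartment denominators."""
    present = (ct.P.fillna(0.0) > 0).sum(axis=0)
    keep = present.index[present >= min_patients]
    if keep.empty:
        raise ValueError("all clusters dropped by the rare-cluster filter")
    return CompositionTable(P=ct.P[keep], compartments=ct.compartments.loc[keep])


def pattern_pca(
    ct: CompositionTable,
    anchors: Mapping[str, Sequence[str]],
) -> PatternAssignment:
    """PC1 of the z-scored composition matrix, oriented and dichotomized.

    The sign is fixed so the mean loading of the CP2E anchor clusters is
    positive; patients with positive PC1 are CP2E, the rest N3MC.
    """
    Z = ct.Z.fillna(0.0)
    if Z.shape[0] < 4:
        raise ValueError("need >= 4 patients for pattern PCA")
    cp2e_anchors = list(anchors.get("CP2E", []))
    missing = [a for a in cp2e_anchors if a not in Z.columns]
    if missing or not cp2e_anchors:
        raise ValueError(f"anchor clusters absent from composition table: {missing or 'CP2E list empty'}")

    # column-ordering invariance: decompose on a canonically sorted matrix
    Zs = Z[sorted(Z.columns)]
    U, S, Vt = np.linalg.svd(Zs.to_numpy() - Zs.to_numpy().mean(axis=0), full_matrices=False)
    loadings = pd.Series(Vt[0], index=Zs.columns)
    pc1 = pd.Series(U[:, 0] * S[0], index=Zs.index)
    if loadings.loc[cp2e_anchors].mean() < 0:
        loadings = -loadings
        pc1 = -pc1
    group = pd.Series(np.where(pc1 > 0, "CP2E", "N3MC"), index=pc1.index, name="group")
    return PatternAssignment(
        pattern_pc1=pc1.rename("pattern_pc1"),
        group=group,
        loadings=loadings.rename("pc1_loading"),
        anchor_clusters={k: list(v) for k, v in anchors.items()},
    )


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided exact permutation p (enumerates all n!
    orderings of one variable). Intended for small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    rx_c = rx - rx.mean()
    denom = math.sqrt((rx_c**2).sum())
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        ryp = ry[list(perm)]
        ryp_c = ryp - ryp.mean()
        d = denom * math.sqrt((ryp_c**2).sum())
        r = float(rx_c @ ryp_c) / d if d > 0 else 0.0
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


def correlation_network(
    ct: CompositionTable,
    rho_min: float = 0.7,
    p_max: float = 0.05,
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Spearman correlation edges between cluster proportions across patients.

    All cluster pairs are tested on patients with complete values; retained
    edges satisfy rho > *rho_min* (positive only) and p < *p_max*. P-values
    are exact permutation when n <= *exact_max_n*, t-approximation otherwise.
    Constant columns are skipped with a note.
    """
    P = ct.P
    if P.shape[0] < 5:
        raise ValueError("need >= 5 patients for a meaningful Spearman p")
    rows = []
    for a, b in combinations(P.columns, 2):
        sub = P[[a, b]].dropna()
        n = len(sub)
        if n < 5:
            continue
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant proportions for pair ({a}, {b}); skipped")
            continue
        if n <= exact_max_n:
            rho, p = spearman_exact_p(x, y)
        else:
            res = stats.spearmanr(x, y)
            rho, p = float(res.statistic), float(res.pvalue)
        if rho > rho_min and p < p_max:
            rows.append({"cluster_a": a, "cluster_b": b, "rho": rho, "p": p})
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "rho", "p"])


def assemble_pattern_signatures(
    markers: Mapping[str, GeneSignature],
    membership: Mapping[str, Sequence[str]],
) -> dict[str, GeneSignature]:
    """Union of member-cluster marker genes per pattern, with genes occurring
    in both patterns removed from both (disjointness enforced)."""
    unions: dict[str, list[str]] = {}
    for pattern, clusters in membership.items():
        genes: list[str] = []
        for c in clusters:
            if c not in markers:
                raise ValueError(f"no marker signature for member cluster {c!r}")
            for g in markers[c].genes:
                if g not in genes:
                    genes.append(g)
        unions[pattern] = genes
    names = list(unions)
    shared: set[str] = set()
    for a, b in combinations(names, 2):
        shared |= set(unions[a]) & set(unions[b])
    out = {}
    for pattern, genes in unions.items():
        kept = [g for g in genes if g not in shared]
        if not kept:
            raise ValueError(f"pattern {pattern!r} signature is empty after deduplication")
        out[pattern] = GeneSignature(name=pattern, genes=kept, direction="up")
    return out


def reduce_signature(
    signatures: Mapping[str, GeneSignature],
    markers: Mapping[str, GeneSignature],
    membership: Mapping[str, Sequence[str]],
    k_total: int = 20,
) -> dict[str, GeneSignature]:
    """Compact k_total-gene signature pair (k_total/2 genes per pattern).

    Member clusters contribute round-robin, each adding its top-ranked unused
    marker that survived into the pattern signature, until the per-pattern
    budget fills. Deterministic.
    """
    budget = k_total // 2
    out = {}
    for pattern, sig in signatures.items():
        allowed = set(sig.genes)
        queues = [
            [g for g in markers[c].genes if g in allowed]
            for c in membership[pattern]
            if c in markers
        ]
        chosen: list[str] = []
        while len(chosen) < budget and any(queues):
            for q in queues:
                while q and (q[0] in chosen or q[0] not in allowed):
                    q.pop(0)
                if q and len(chosen) < budget:
                    chosen.append(q.pop(0))
        if len(chosen) < budget:
            warnings.warn(
                f"pattern {pattern!r}: only {len(chosen)} genes available for the "
                f"reduced signature (budget {budget})"
            )
        out[pattern] = GeneSignature(name=f"{pattern}_reduced", genes=chosen, direction="up")
    return out
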