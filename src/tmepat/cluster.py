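"""Dimensionality reduction, SNN-graph clustering, and cell-type annotation.

Cells are embedded by PCA on z-scored highly-variable genes, joined into a
shared-nearest-neighbor graph whose edge weights are Jaccard overlaps of
k-nearest-neighbor sets, partitioned by modularity (Louvain), annotated by the
best-scoring reference signature, and epithelial clusters dominated by
tumor-tissue cells are called tumor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import GeneSignature, NormMatrix
from .scoring import ModuleScoreParams, module_score

logger = logging.getLogger("tmepat")

__all__ = [
    "ClusterAssignment",
    "pca_embed",
    "build_snn",
    "cluster_graph",
    "annotate_clusters",
    "call_tumor_clusters",
]


@dataclass
class ClusterAssignment:
    """Cluster labels per cell plus per-cluster annotation."""

    cells: list[str]
    labels: np.ndarray  # int cluster id per cell
    cluster_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # cluster_table index: cluster id; columns: cell_type, compartment, tumor_call

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.cells):
            raise ValueError("one label per cell required")
        if self.cluster_table.empty:
            ids = np.unique(self.labels)
            self.cluster_table = pd.DataFrame(
                {"cell_type": "", "compartment": "", "tumor_call": "n/a"}, index=ids
            )

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def cell_series(self, column: str) -> pd.Series:
        """Per-cell values of a cluster_table column."""
        return pd.Series(
            self.cluster_table[column].reindex(self.labels).to_numpy(),
            index=self.cells, name=column,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.labels}, index=self.cells)
        for col in self.cluster_table.columns:
            df[col] = self.cluster_table[col].reindex(self.labels).to_numpy()
        return df


def pca_embed(
    nm: NormMatrix,
    hvg: Sequence[int] | None,
    n_pcs: int = 15,
    clip: float = 10.0,
) -> np.ndarray:
    """Cell x PC score matrix from z-scored (clipped at +/-*clip*) HVG expression.

    Scores are ordered by decreasing explained variance. The sign of each
    component is fixed so its score of largest absolute value is positive,
    which makes the embedding deterministic and invariant to a global sign
    flip of the input.
    """
    idx = np.arange(nm.shape[0]) if hvg is None else np.asarray(list(hvg), dtype=int)
    if idx.size == 0:
        raise ValueError("hvg list is empty")
    X = np.asarray(nm.X[idx].todense(), dtype=float).T  # cells x genes
    mu = X.mean(axis=0, keepdims=True)
    sd = np.clip(X.std(axis=0, ddof=0, keepdims=True), 1e-8, None)
    Z = np.clip((X - mu) / sd, -clip, clip)

    max_pcs = min(Z.shape[0] - 1, Z.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} clamped to {max_pcs}")
        n_pcs = max_pcs
    solver = "arpack" if 0 < n_pcs < min(Z.shape) else "full"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(Z)
    # deterministic sign: largest-|score| entry of each PC is positive
    flip = scores[np.abs(scores).argmax(axis=0), np.arange(scores.shape[1])] < 0
    scores[:, flip] *= -1
    return scores


def build_snn(pcs: np.ndarray, k: int = 20, prune: float = 1.0 / 15.0) -> nx.Graph:
    """Shared-nearest-neighbor graph in PC space.

    Each cell's neighbor set is itself plus its ``k - 1`` nearest neighbors
    (Euclidean). Edge weight is the Jaccard overlap of the two sets; edges
    below *prune* are discarded.
    """
    n = pcs.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, knn = nn.kneighbors(pcs)  # includes self as the first neighbor
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, knn.ravel())), shape=(n, n))
    A.data = np.minimum(A.data, 1.0)  # guard duplicate neighbor entries
    inter = A @ A.T
    inter = sp.triu(inter.tocoo(), k=1)
    jac = inter.data / (2.0 * k - inter.data)
    keep = jac >= prune
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from(
        zip(inter.row[keep].tolist(), inter.col[keep].tolist(), jac[keep].tolist())
    )
    return g


def cluster_graph(g: nx.Graph, resolution: float = 0.8, seed: int = 0,
                  cells: Sequence[str] | None = None) -> ClusterAssignment:
    """Louvain modularity communities on the SNN graph; deterministic per seed.

    Cluster ids are relabeled by decreasing community size (ties by smallest
    member node) so labels are stable across runs.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(g, weight="weight",
                                             resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for cid, members in enumerate(comms):
        labels[list(members)] = cid
    names = list(cells) if cells is not None else [str(i) for i in range(len(labels))]
    return ClusterAssignment(cells=names, labels=labels)


def annotate_clusters(
    ca: ClusterAssignment,
    nm: NormMatrix,
    references: Sequence[GeneSignature],
    params: ModuleScoreParams | None = None,
) -> ClusterAssignment:
    """Label each cluster with the reference signature of maximal mean module score.

    The compartment comes from the winning signature's tag. Ties go to the
    signature with the larger margin over the runner-up, then lexicographic.
    Clusters whose best score is <= 0 are labeled ``unassigned``.
    """
    if not references:
        raise ValueError("empty reference list")
    params = params or ModuleScoreParams()
    per_ref = {}
    for sig in references:
        per_ref[sig.name] = module_score(nm, sig, params)
    score_df = pd.DataFrame(per_ref, index=nm.cells)
    cluster_means = score_df.groupby(pd.Series(ca.labels, index=nm.cells)).mean()

    comp_by_ref = {s.name: (s.compartment or "") for s in references}
    table = ca.cluster_table.copy()
    for cid, row in cluster_means.iterrows():
        ranked = row.sort_values(ascending=False, kind="stable")
        best = ranked.index[0]
        if len(ranked) > 1 and np.isclose(ranked.iloc[0], ranked.iloc[1]):
            tied = sorted(ranked.index[np.isclose(ranked.values, ranked.iloc[0])])
            best = tied[0]
        if ranked.iloc[0] <= 0:
            warnings.warn(f"cluster {cid}: best reference score <= 0; labeled unassigned")
            table.loc[cid, ["cell_type", "compartment"]] = ["unassigned", ""]
        else:
            table.loc[cid, ["cell_type", "compartment"]] = [best, comp_by_ref[best]]
    return ClusterAssignment(cells=ca.cells, labels=ca.labels, cluster_table=table)


def call_tumor_clusters(
    ca: ClusterAssignment,
    meta: pd.DataFrame,
    min_tumor_frac: float = 0.9,
) -> ClusterAssignment:
    """Call epithelial clusters tumor when their tumor-tissue cell fraction
    reaches *min_tumor_frac*; other epithelial clusters are normal, the rest n/a."""
    tissue = meta.loc[ca.cells, "tissue"].to_numpy()
    table = ca.cluster_table.copy()
    for cid in ca.cluster_ids:
        if table.loc[cid, "compartment"] != "epithelial":
            table.loc[cid, "tumor_call"] = "n/a"
            continue
        in_c = ca.labels == cid
        frac_tumor = float(np.mean(tissue[in_c] == "tumor"))
        table.loc[cid, "tumor_call"] = "tumor" if frac_tumor >= min_tumor_frac else "normal"
    return ClusterAssignment(cells=ca.cells, labels=ca.labels, cluster_table=table)
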