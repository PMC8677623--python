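"""Readers/writers for the standard formats the pipeline touches.

Single-cell counts travel as 10x Genomics triplets (Matrix Market ``matrix.mtx``
plus ``features.tsv``/``genes.tsv`` and ``barcodes.tsv``); gene sets as GMT or
two-column TSV. Gene identity is by symbol throughout — Ensembl-style IDs in a
features file are retained as metadata but never used for matching, because all
signatures downstream are symbol lists.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("tmepat")

__all__ = [
    "CountMatrix",
    "NormMatrix",
    "GeneSignature",
    "RunConfig",
    "FormatError",
    "IntegrityError",
    "read_10x_mtx",
    "write_10x_mtx",
    "load_gene_sets",
    "save_gene_sets_gmt",
    "make_unique",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(ValueError):
    """Files parse individually but are mutually inconsistent."""


def make_unique(names: Sequence[str]) -> list[str]:
    """Deduplicate *names* by suffixing later occurrences with ``.1``, ``.2``, ...

    The first occurrence keeps its name. Deterministic and order-preserving.
    """
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            while new in seen:  # avoid colliding with a literal "X.1" input
                seen[name] += 1
                new = f"{name}.{seen[name]}"
            out.append(new)
            seen[new] = 0
        else:
            seen[name] = 0
            out.append(name)
    return out


@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix.

    ``counts`` is genes x cells (CSR), non-negative integers. Gene symbols and
    barcodes are unique after loading; ``gene_ids`` carries the first column of
    a features file when one was read.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise IntegrityError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError("duplicate gene symbols")
        if len(set(self.cells)) != len(self.cells):
            raise IntegrityError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
        )


@dataclass
class NormMatrix:
    """Normalized (log) expression, genes x cells, sparse with zeros preserved."""

    genes: list[str]
    cells: list[str]
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X, dtype=np.float64)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise IntegrityError("X shape does not match genes x cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.genes)}
        return np.array([lut[s] for s in symbols if s in lut], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "NormMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            X=self.X[:, idx],
        )


@dataclass
class GeneSignature:
    """Named ordered gene list with an optional direction/compartment tag."""

    name: str
    genes: list[str]
    direction: str = "none"  # up | bidirectional-positive | bidirectional-negative | none
    compartment: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    The seed fully determines every stochastic stage (control-gene sampling,
    graph clustering, permutation tests, the synthetic generator).
    """

    seed: int = 0
    # QC (inclusive count bounds, strict fraction bounds)
    min_genes: int = 500
    max_genes: int = 10_000
    min_umi: int = 1_000
    max_umi: int = 100_000
    max_mito_frac: float = 0.30
    max_hb_frac: float = 0.05
    # normalization / HVG
    norm_scale: float = 1e4
    n_hvg: int = 3000
    # embedding / clustering
    n_pcs_global: int = 15
    n_pcs_subset: int = 20
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 0.8
    # tumor calling
    min_tumor_frac: float = 0.9
    # module score
    n_bins: int = 24
    n_ctrl: int = 100
    # markers
    logfc_min: float = 0.25
    min_pct: float = 0.25
    min_diff_pct: float = 0.25
    # signatures
    n_axis_genes: int = 30
    min_pattern_patients: int = 3
    reduced_signature_size: int = 20
    # ssGSEA
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    # interactions
    n_perm: int = 1000
    expr_frac: float = 0.1


# ---------------------------------------------------------------------------
# 10x triplet I/O
# ---------------------------------------------------------------------------

def _find(dir_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dir_path / name
            if p.exists():
                return p
    raise FormatError(f"none of {list(stems)} found in {dir_path}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_10x_mtx(dir_path: str | Path) -> CountMatrix:
    """Read a 10x triplet directory into a :class:`CountMatrix`.

    Matrix Market coordinates are 1-based on disk and 0-based internally
    (scipy handles the conversion). Duplicate gene symbols are made unique by
    suffixing; duplicate barcodes are an integrity error.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, ["matrix.mtx"])
    feat_path = _find(dir_path, ["features.tsv", "genes.tsv"])
    bc_path = _find(dir_path, ["barcodes.tsv"])

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()

    if feats.shape[1] >= 2:
        gene_ids = feats[0].tolist()
        symbols = feats[1].tolist()
    else:
        gene_ids = None
        symbols = feats[0].tolist()

    if mat.shape[0] != len(symbols):
        raise IntegrityError(
            f"matrix has {mat.shape[0]} rows but features file lists {len(symbols)} genes"
        )
    if mat.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix has {mat.shape[1]} columns but barcodes file lists {len(barcodes)} cells"
        )

    cm = CountMatrix(
        genes=make_unique(symbols),
        cells=barcodes,
        counts=sp.csr_matrix(mat),
        gene_ids=gene_ids,
    )
    logger.info("read_10x_mtx: %d genes x %d cells from %s", *cm.shape, dir_path)
    return cm


def write_10x_mtx(cm: CountMatrix, dir_path: str | Path) -> None:
    """Write *cm* as a plain-text 10x triplet directory (lossless round-trip)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(cm.counts))
    ids = cm.gene_ids if cm.gene_ids is not None else cm.genes
    pd.DataFrame({0: ids, 1: cm.genes, 2: ["Gene Expression"] * len(cm.genes)}).to_csv(
        dir_path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({0: cm.cells}).to_csv(
        dir_path / "barcodes.tsv", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def _dedup_preserve(genes: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for g in genes:
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def _iter_gmt(path: Path) -> Iterator[tuple[str, list[str]]]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line has <2 fields")
            yield parts[0], _dedup_preserve(parts[2:])


def load_gene_sets(path: str | Path, format: str | None = None) -> list[GeneSignature]:
    """Load gene signatures from a GMT file or a two-column (set, gene) TSV.

    Format is inferred from the extension when not given. Empty sets are
    skipped with a warning; duplicate genes within one set are deduplicated
    with order preserved.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.name.rstrip(".gz").endswith(".gmt") else "tsv"
    sigs: list[GeneSignature] = []
    if format == "gmt":
        for name, genes in _iter_gmt(path):
            if not genes:
                warnings.warn(f"gene set {name!r} is empty; skipped")
                continue
            sigs.append(GeneSignature(name=name, genes=genes))
    elif format == "tsv":
        order: list[str] = []
        by_name: dict[str, list[str]] = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
                name, gene = parts[0], parts[1]
                if name not in by_name:
                    by_name[name] = []
                    order.append(name)
                by_name[name].append(gene)
        for name in order:
            genes = _dedup_preserve(by_name[name])
            if not genes:
                warnings.warn(f"gene set {name!r} is empty; skipped")
                continue
            sigs.append(GeneSignature(name=name, genes=genes))
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    logger.info("load_gene_sets: %d sets from %s", len(sigs), path)
    return sigs


def save_gene_sets_gmt(sigs: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, sig.direction, *sig.genes]) + "\n")
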