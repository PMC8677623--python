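"""Synthetic single-cell and bulk cohorts with planted microenvironment patterns.

The generator emulates a two-archetype lung-adenocarcinoma study design:

* per patient, cell-type counts are Dirichlet-multinomial draws whose
  concentrations depend on the patient's microenvironmental archetype
  (N3MC: normal-like myofibroblasts, non-inflammatory monocyte-derived
  macrophages, NK cells, myeloid DCs, conventional T cells elevated;
  CP2E: cancer-associated myofibroblasts, proinflammatory macrophages,
  plasmacytoid DCs, exhausted CD8 T cells elevated);
* per cell, UMI counts are negative-binomial (gamma-Poisson) with a
  lognormal library size and cell-type marker genes scaled by
  ``exp(marker_logfc)``;
* tumor epithelial cells carry a continuous differentiation latent
  ``u`` in [0, 1] coupled to the archetype; alveolar/club-program genes
  scale with ``u`` and a dedicated undifferentiated program with ``1 - u``;
* a configurable fraction of cells is corrupted to violate exactly one QC
  rule each (low gene count, mitochondrial fraction > 0.30, hemoglobin
  fraction > 0.05), so filter attribution is testable;
* bulk samples are pseudobulk mixtures of the same programs with planted
  exponential survival whose hazard depends on archetype.

Every generated cell and sample has a truth record; the objects consumed by
the pipeline (counts, cell metadata, bulk expression/survival) carry no truth
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix, GeneSignature

__all__ = [
    "CellTypeProgram",
    "ArchetypeSpec",
    "SyntheticTruth",
    "MITO_GENES",
    "HEMOGLOBIN_GENES",
    "N3MC_ANCHORS",
    "CP2E_ANCHORS",
    "default_programs",
    "default_archetypes",
    "normal_tissue_alpha",
    "simulate_sc_cohort",
    "simulate_bulk_cohort",
]

# Mitochondrial genes follow the MT- symbol prefix convention; hemoglobin
# genes are the explicit four-gene list commonly used for erythrocyte QC.
MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
HEMOGLOBIN_GENES = ["HBA1", "HBA2", "HBB", "HBD"]

N3MC_ANCHORS = [
    "MyoF_normal_like", "Mac_noninflammatory", "NK", "DC_myeloid", "T_conventional",
]
CP2E_ANCHORS = [
    "MyoF_cancer_associated", "Mac_proinflammatory", "DC_plasmacytoid", "CD8_exhausted",
]

NB_DISPERSION = 0.3  # typical overdispersion for 10x UMI data
LIBSIZE_MEANLOG = 9.0
LIBSIZE_SDLOG = 0.3
U_SD = 0.15  # sd of the tumor-cell differentiation latent around its archetype center


@dataclass
class CellTypeProgram:
    """Expression program of one cell type: dedicated markers on a shared baseline."""

    name: str
    compartment: str  # epithelial | myeloid | lymphoid | endothelial | fibroblastic
    marker_genes: list[str]
    marker_logfc: float = 2.0
    baseline_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.marker_logfc <= 0:
            raise ValueError("marker_logfc must be > 0")


@dataclass
class ArchetypeSpec:
    """A microenvironmental archetype: composition prior + differentiation center."""

    name: str  # N3MC | CP2E
    proportion_alpha: dict[str, float]
    differentiation_mean: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.proportion_alpha.values()):
            raise ValueError("Dirichlet concentrations must be > 0")
        if not 0.0 <= self.differentiation_mean <= 1.0:
            raise ValueError("differentiation_mean must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Complete ground truth for a generated cohort (test harness only)."""

    cells: pd.DataFrame  # barcode, patient, tissue, archetype, cell_type, compartment, u, qc_fail_rule
    patients: pd.DataFrame  # patient, archetype
    signatures: dict[str, list[str]]  # planted gene programs by name
    programs: list[CellTypeProgram] = field(default_factory=list)
    samples: pd.DataFrame | None = None  # bulk: sample, archetype, hazard_mult

    def reference_signatures(self) -> list[GeneSignature]:
        """Planted marker sets as annotation references with compartment tags."""
        return [
            GeneSignature(name=p.name, genes=list(p.marker_genes),
                          direction="up", compartment=p.compartment)
            for p in self.programs
        ]


def default_programs(n_markers: int = 10) -> list[CellTypeProgram]:
    """The 16 default cell-type programs across the five compartments."""
    spec = [
        ("AT1", "epithelial"),
        ("AT2", "epithelial"),
        ("Club", "epithelial"),
        ("Tumor", "epithelial"),
        ("Mac_noninflammatory", "myeloid"),
        ("Mac_proinflammatory", "myeloid"),
        ("DC_myeloid", "myeloid"),
        ("DC_plasmacytoid", "myeloid"),
        ("T_conventional", "lymphoid"),
        ("CD8_exhausted", "lymphoid"),
        ("NK", "lymphoid"),
        ("B", "lymphoid"),
        ("Endo_blood", "endothelial"),
        ("Endo_lymphatic", "endothelial"),
        ("MyoF_normal_like", "fibroblastic"),
        ("MyoF_cancer_associated", "fibroblastic"),
    ]
    return [
        CellTypeProgram(
            name=name,
            compartment=comp,
            marker_genes=[f"{name}.M{i + 1:02d}" for i in range(n_markers)],
        )
        for name, comp in spec
    ]


# Base tumor-tissue Dirichlet concentrations, before the archetype shift.
_TUMOR_BASE_ALPHA = {
    "Tumor": 25.0, "AT1": 2.0, "AT2": 3.0, "Club": 2.0,
    "Mac_noninflammatory": 8.0, "Mac_proinflammatory": 8.0,
    "DC_myeloid": 4.0, "DC_plasmacytoid": 3.0,
    "T_conventional": 8.0, "CD8_exhausted": 6.0, "NK": 5.0, "B": 4.0,
    "Endo_blood": 5.0, "Endo_lymphatic": 2.0,
    "MyoF_normal_like": 5.0, "MyoF_cancer_associated": 5.0,
}


def default_archetypes(shift: float = 2.0) -> list[ArchetypeSpec]:
    """N3MC and CP2E archetypes with a *shift*-fold concentration contrast
    on each pattern's anchor clusters (own anchors x shift, rival anchors / shift)."""

    def shifted(own: Sequence[str], rival: Sequence[str]) -> dict[str, float]:
        alpha = dict(_TUMOR_BASE_ALPHA)
        for c in own:
            alpha[c] *= shift
        for c in rival:
            alpha[c] /= shift
        return alpha

    return [
        ArchetypeSpec("N3MC", shifted(N3MC_ANCHORS, CP2E_ANCHORS), differentiation_mean=0.75),
        ArchetypeSpec("CP2E", shifted(CP2E_ANCHORS, N3MC_ANCHORS), differentiation_mean=0.25),
    ]


def normal_tissue_alpha() -> dict[str, float]:
    """Archetype-independent composition prior for normal lung tissue."""
    return {
        "AT1": 18.0, "AT2": 28.0, "Club": 12.0,
        "Mac_noninflammatory": 6.0, "Mac_proinflammatory": 2.0,
        "DC_myeloid": 3.0, "DC_plasmacytoid": 1.0,
        "T_conventional": 14.0, "CD8_exhausted": 1.0, "NK": 6.0, "B": 4.0,
        "Endo_blood": 6.0, "Endo_lymphatic": 2.0,
        "MyoF_normal_like": 5.0, "MyoF_cancer_associated": 0.5,
    }


def _gene_universe(
    programs: Sequence[CellTypeProgram],
    n_background_genes: int,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, dict[str, list[str]]]:
    """Assemble the gene list and baseline weight vector.

    Returns (genes, baseline_weights, planted) where ``planted`` maps the
    alveolar/undifferentiated tumor programs to their gene lists.
    """
    marker_genes = [g for p in programs for g in p.marker_genes]
    if len(set(marker_genes)) != len(marker_genes):
        raise ValueError("marker genes must be disjoint across programs")
    undiff_genes = [f"UND.G{i + 1:02d}" for i in range(30)]
    bg_genes = [f"BG.{i + 1:04d}" for i in range(n_background_genes)]
    genes = marker_genes + undiff_genes + bg_genes + MITO_GENES + HEMOGLOBIN_GENES

    w = np.empty(len(genes))
    n_mk, n_ud = len(marker_genes), len(undiff_genes)
    w[:n_mk] = [p.baseline_mean for p in programs for _ in p.marker_genes]
    w[n_mk:n_mk + n_ud] = 1.0
    w[n_mk + n_ud:n_mk + n_ud + n_background_genes] = rng.gamma(2.0, 1.0, n_background_genes)
    total_so_far = w[:n_mk + n_ud + n_background_genes].sum()
    # mitochondrial baseline ~8% of reads, hemoglobin ~0.2%
    w[-17:-4] = 0.08 * total_so_far / (1 - 0.08) / len(MITO_GENES)
    w[-4:] = 0.002 * total_so_far / len(HEMOGLOBIN_GENES)

    alveolar = [g for p in programs if p.name in ("AT1", "AT2", "Club") for g in p.marker_genes]
    planted = {"alveolar_club_like": alveolar, "undifferentiated": undiff_genes}
    return genes, w, planted


def _nb_counts(mean: np.ndarray, rng: np.random.Generator,
               dispersion: float = NB_DISPERSION) -> np.ndarray:
    """Gamma-Poisson draw with var = m + dispersion * m^2."""
    lam = rng.gamma(1.0 / dispersion, dispersion * np.clip(mean, 1e-12, None))
    return rng.poisson(lam)


def simulate_sc_cohort(
    n_patients: int = 10,
    cells_per_patient: int = 500,
    programs: Sequence[CellTypeProgram] | None = None,
    archetypes: Sequence[ArchetypeSpec] | None = None,
    qc_artifact_frac: float = 0.0,
    seed: int = 0,
    n_background_genes: int = 3000,
    normal_fraction: float = 0.5,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a multi-patient single-cell cohort with planted archetypes.

    Each patient contributes paired normal and tumor tissue cells
    (``normal_fraction`` of ``cells_per_patient`` from normal tissue). Patients
    alternate between the supplied archetypes so both patterns are covered.

    Returns ``(counts, meta, truth)`` where ``meta`` is the per-cell table
    (barcode, patient, tissue) the pipeline is allowed to see.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients (one per archetype)")
    programs = list(programs) if programs is not None else default_programs()
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    if not archetypes:
        raise ValueError("at least one archetype required")
    compartments = {p.compartment for p in programs}
    if compartments != {"epithelial", "myeloid", "lymphoid", "endothelial", "fibroblastic"}:
        raise ValueError(f"programs must cover all five compartments, got {sorted(compartments)}")

    rng = np.random.default_rng(seed)
    genes, w_base, planted = _gene_universe(programs, n_background_genes, rng)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    prog_by_name = {p.name: p for p in programs}
    normal_alpha = normal_tissue_alpha()
    for name in normal_alpha:
        if name not in prog_by_name:
            raise ValueError(f"normal-tissue alpha references unknown program {name!r}")

    alveolar_idx = np.array([gene_idx[g] for g in planted["alveolar_club_like"]])
    undiff_idx = np.array([gene_idx[g] for g in planted["undifferentiated"]])
    mt_idx = np.array([gene_idx[g] for g in MITO_GENES])
    hb_idx = np.array([gene_idx[g] for g in HEMOGLOBIN_GENES])

    n_normal = int(round(cells_per_patient * normal_fraction))
    n_qc = int(round(cells_per_patient * qc_artifact_frac))

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    patient_rows: list[dict] = []

    for pi in range(n_patients):
        patient = f"P{pi + 1:03d}"
        arch = archetypes[pi % len(archetypes)]
        patient_rows.append({"patient": patient, "archetype": arch.name})

        # --- cell types: Dirichlet-multinomial per tissue
        cell_types: list[str] = []
        tissues: list[str] = []
        for tissue, n_cells, alpha_map in (
            ("normal", n_normal, normal_alpha),
            ("tumor", cells_per_patient - n_normal, arch.proportion_alpha),
        ):
            names = [n for n in alpha_map if n in prog_by_name]
            props = rng.dirichlet([alpha_map[n] for n in names])
            counts_per_type = rng.multinomial(n_cells, props)
            for name, k in zip(names, counts_per_type):
                cell_types.extend([name] * int(k))
                tissues.extend([tissue] * int(k))

        # --- expected expression weight per cell
        W = np.tile(w_base, (cells_per_patient, 1))
        u_vals = np.full(cells_per_patient, np.nan)
        boost = {}
        for j, ct in enumerate(cell_types):
            prog = prog_by_name[ct]
            if ct not in boost:
                boost[ct] = (
                    np.array([gene_idx[g] for g in prog.marker_genes]),
                    np.exp(prog.marker_logfc),
                )
            midx, mfac = boost[ct]
            W[j, midx] *= mfac
            if ct == "Tumor":
                u = float(np.clip(rng.normal(arch.differentiation_mean, U_SD), 0.0, 1.0))
                u_vals[j] = u
                lfc_fac = np.exp(prog.marker_logfc) - 1.0
                W[j, alveolar_idx] *= 1.0 + u * lfc_fac
                W[j, undiff_idx] *= 1.0 + (1.0 - u) * lfc_fac

        lib = rng.lognormal(LIBSIZE_MEANLOG, LIBSIZE_SDLOG, cells_per_patient)
        mean = W / W.sum(axis=1, keepdims=True) * lib[:, None]
        counts = _nb_counts(mean, rng)

        # --- QC artifacts: exactly n_qc cells, each violating exactly one rule
        qc_rules = np.array([""] * cells_per_patient, dtype=object)
        if n_qc:
            victims = rng.choice(cells_per_patient, size=n_qc, replace=False)
            rules = ["low_genes", "high_mito", "high_hb"]
            safe = np.setdiff1d(
                np.arange(n_genes), np.concatenate([mt_idx, hb_idx])
            )
            for k, j in enumerate(victims):
                rule = rules[k % 3]
                qc_rules[j] = rule
                if rule == "low_genes":
                    # <500 genes detected but UMI, mito and hb still in range
                    row = np.zeros(n_genes, dtype=counts.dtype)
                    chosen = rng.choice(safe, size=60, replace=False)
                    row[chosen] = rng.multinomial(1500, np.full(60, 1 / 60))
                    row[mt_idx[0]] = 80  # mito frac ~5%, keeps rule count at one
                    counts[j] = row
                elif rule == "high_mito":
                    # push mito fraction to ~0.45 (> 0.30), all else unchanged
                    other = counts[j].sum() - counts[j, mt_idx].sum()
                    counts[j, mt_idx] = rng.multinomial(
                        int(np.ceil(0.45 / 0.55 * other)), np.full(len(mt_idx), 1 / len(mt_idx))
                    )
                else:
                    # push hemoglobin fraction to ~0.12 (> 0.05)
                    other = counts[j].sum() - counts[j, hb_idx].sum()
                    counts[j, hb_idx] = rng.multinomial(
                        int(np.ceil(0.12 / 0.88 * other)), np.full(len(hb_idx), 1 / len(hb_idx))
                    )

        barcodes = [f"{patient}_C{j + 1:04d}" for j in range(cells_per_patient)]
        blocks.append(sp.csr_matrix(counts))  # cells x genes blocks
        for j in range(cells_per_patient):
            meta_rows.append({"barcode": barcodes[j], "patient": patient, "tissue": tissues[j]})
            truth_rows.append({
                "barcode": barcodes[j], "patient": patient, "tissue": tissues[j],
                "archetype": arch.name, "cell_type": cell_types[j],
                "compartment": prog_by_name[cell_types[j]].compartment,
                "u": u_vals[j], "qc_fail_rule": qc_rules[j],
            })

    counts_all = sp.vstack(blocks).T.tocsr()  # genes x cells
    meta = pd.DataFrame(meta_rows).set_index("barcode")
    truth = SyntheticTruth(
        cells=pd.DataFrame(truth_rows).set_index("barcode"),
        patients=pd.DataFrame(patient_rows),
        signatures={**planted, **{p.name: list(p.marker_genes) for p in programs}},
        programs=programs,
    )
    cm = CountMatrix(genes=genes, cells=meta.index.tolist(), counts=counts_all)
    return cm, meta, truth


def simulate_bulk_cohort(
    n_samples: int = 200,
    programs: Sequence[CellTypeProgram] | None = None,
    archetypes: Sequence[ArchetypeSpec] | None = None,
    survival_beta: float = np.log(2.0),
    censor_rate: float = 0.3,
    seed: int = 0,
    n_background_genes: int = 3000,
    baseline_hazard: float = 0.05,
    noise_sd: float = 0.3,
):
    """Generate a bulk cohort of pseudobulk mixtures with planted survival.

    Each sample mixes the cell-type program mean-expression vectors with
    archetype-specific Dirichlet proportions, is log2-transformed with
    lognormal noise, and gets an exponential survival time whose hazard is
    multiplied by ``exp(survival_beta)`` for CP2E samples. Censoring times are
    independent exponentials tuned to the requested censoring rate.

    Returns ``(cohort, truth)``; the cohort's expression and survival tables
    carry no truth fields.
    """
    from .survival import BulkCohort  # local import to avoid a cycle

    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    if not np.isfinite(survival_beta):
        raise ValueError("survival_beta must be finite")
    programs = list(programs) if programs is not None else default_programs()
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    if len(archetypes) < 2:
        raise ValueError("bulk simulation needs both archetypes")

    rng = np.random.default_rng(seed)
    genes, w_base, planted = _gene_universe(programs, n_background_genes, rng)
    gene_idx = {g: i for i, g in enumerate(genes)}
    alveolar_idx = np.array([gene_idx[g] for g in planted["alveolar_club_like"]])
    undiff_idx = np.array([gene_idx[g] for g in planted["undifferentiated"]])

    # per-archetype program profiles (tumor program uses the archetype's mean u)
    profiles: dict[str, dict[str, np.ndarray]] = {}
    for arch in archetypes:
        by_prog = {}
        for p in programs:
            w = w_base.copy()
            midx = np.array([gene_idx[g] for g in p.marker_genes])
            w[midx] *= np.exp(p.marker_logfc)
            if p.name == "Tumor":
                u = arch.differentiation_mean
                lfc_fac = np.exp(p.marker_logfc) - 1.0
                w[alveolar_idx] *= 1.0 + u * lfc_fac
                w[undiff_idx] *= 1.0 + (1.0 - u) * lfc_fac
            by_prog[p.name] = w / w.sum()
        profiles[arch.name] = by_prog

    arch_assign = [archetypes[i % len(archetypes)] for i in range(n_samples)]
    X = np.empty((n_samples, len(genes)))
    hazards = np.empty(n_samples)
    rows = []
    for i, arch in enumerate(arch_assign):
        names = [n for n in arch.proportion_alpha]
        props = rng.dirichlet([arch.proportion_alpha[n] for n in names])
        mix = np.zeros(len(genes))
        for name, pr in zip(names, props):
            mix += pr * profiles[arch.name][name]
        X[i] = np.log2(1.0 + mix * 1e5) + rng.normal(0.0, noise_sd, len(genes))
        hazards[i] = baseline_hazard * np.exp(survival_beta * (arch.name == "CP2E"))
        rows.append({"sample": f"S{i + 1:04d}", "archetype": arch.name,
                     "hazard_mult": float(np.exp(survival_beta * (arch.name == "CP2E")))})

    event_t = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        if censor_rate >= 1:
            raise ValueError("censor_rate must be < 1")
        cens_hazard = censor_rate / (1.0 - censor_rate) * hazards.mean()
        cens_t = rng.exponential(1.0 / cens_hazard, n_samples)
    else:
        cens_t = np.full(n_samples, np.inf)
    time = np.minimum(event_t, cens_t)
    event = (event_t <= cens_t).astype(int)

    samples = [r["sample"] for r in rows]
    survival = pd.DataFrame({"time": time, "event": event}, index=samples)
    cohort = BulkCohort(samples=samples, genes=genes, X=X, survival=survival)
    truth = SyntheticTruth(
        cells=pd.DataFrame(), patients=pd.DataFrame(),
        signatures={**planted, **{p.name: list(p.marker_genes) for p in programs}},
        programs=programs,
        samples=pd.DataFrame(rows).set_index("sample"),
    )
    return cohort, truth
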