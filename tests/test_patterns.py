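from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmepat.cluster import ClusterAssignment
from tmepat.core_io import GeneSignature, RunConfig
from tmepat.patterns import (
    CompositionTable,
    assemble_pattern_signatures,
    compute_proportions,
    correlation_network,
    filter_rare_clusters,
    pattern_pca,
    reduce_signature,
)
from tmepat.pipeline import recover_patterns
from tmepat import synthetic


def make_assignment(records):
    """records: list of (barcode, cell_type, compartment, patient, tissue)."""
    cells = [r[0] for r in records]
    types = sorted({r[1] for r in records})
    labels = np.array([types.index(r[1]) for r in records])
    table = pd.DataFrame(
        {
            "cell_type": types,
            "compartment": [next(x[2] for x in records if x[1] == t) for t in types],
            "tumor_call": "n/a",
        },
        index=range(len(types)),
    )
    ca = ClusterAssignment(cells=cells, labels=labels, cluster_table=table)
    meta = pd.DataFrame(
        {"patient": [r[3] for r in records], "tissue": [r[4] for r in records]},
        index=cells,
    )
    return ca, meta


def test_proportions_simple_tally():
    records = (
        [(f"a{i}", "A", "myeloid", "P1", "tumor") for i in range(30)]
        + [(f"b{i}", "B", "myeloid", "P1", "tumor") for i in range(70)]
    )
    ca, meta = make_assignment(records)
    ct = compute_proportions(ca, meta)
    assert ct.P.loc["P1", "A"] == pytest.approx(0.3)
    assert ct.P.loc["P1", "B"] == pytest.approx(0.7)


def test_proportions_sum_to_one_per_compartment(small_cohort_clean):
    nm, meta, truth = small_cohort_clean
    records = [
        (bc, truth.cells.loc[bc, "cell_type"], truth.cells.loc[bc, "compartment"],
         meta.loc[bc, "patient"], meta.loc[bc, "tissue"])
        for bc in nm.cells
    ]
    ca, meta2 = make_assignment(records)
    ct = compute_proportions(ca, meta2)
    for comp in ct.compartments.unique():
        cols = ct.compartments.index[ct.compartments == comp]
        sums = ct.P[cols].sum(axis=1)
        np.testing.assert_allclose(sums.dropna(), 1.0, atol=1e-9)


def test_normal_tissue_cells_excluded():
    records = (
        [(f"t{i}", "A", "myeloid", "P1", "tumor") for i in range(10)]
        + [(f"n{i}", "B", "myeloid", "P1", "normal") for i in range(90)]
    )
    ca, meta = make_assignment(records)
    ct = compute_proportions(ca, meta)
    assert ct.P.loc["P1", "A"] == pytest.approx(1.0)
    assert "B" not in ct.P.columns or ct.P.loc["P1", "B"] == 0


def rare_table():
    P = pd.DataFrame(
        {
            "common": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
            "in2": [0.2, 0.3, 0, 0, 0, 0, 0, 0, 0, 0],
            "in3": [0.3, 0.2, 0.5, 0, 0, 0, 0, 0, 0, 0],
        },
        index=[f"P{i}" for i in range(10)],
    )
    comp = pd.Series("myeloid", index=P.columns)
    return CompositionTable(P=P, compartments=comp)


def test_rare_cluster_boundary():
    """Clusters in <3 patients are dropped; exactly 3 is kept."""
    out = filter_rare_clusters(rare_table(), min_patients=3)
    assert "in2" not in out.P.columns
    assert set(out.P.columns) == {"common", "in3"}


def test_min_patients_zero_is_identity():
    ct = rare_table()
    out = filter_rare_clusters(ct, min_patients=0)
    assert list(out.P.columns) == list(ct.P.columns)


def test_all_dropped_errors():
    with pytest.raises(ValueError):
        filter_rare_clusters(rare_table(), min_patients=11)


# ---------------------------------------------------------------------------
# pattern PCA
# ---------------------------------------------------------------------------

def composition_from_truth(n_patients=10, seed=1):
    cm, meta, truth = synthetic.simulate_sc_cohort(
        n_patients=n_patients, cells_per_patient=400, seed=seed
    )
    records = [
        (bc, truth.cells.loc[bc, "cell_type"], truth.cells.loc[bc, "compartment"],
         meta.loc[bc, "patient"], meta.loc[bc, "tissue"])
        for bc in cm.cells
    ]
    ca, meta2 = make_assignment(records)
    ct = compute_proportions(ca, meta2)
    return filter_rare_clusters(ct), truth


ANCHORS = {"N3MC": synthetic.N3MC_ANCHORS, "CP2E": synthetic.CP2E_ANCHORS}


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_pattern_pca_recovers_archetypes(seed):
    """Given true compositions, PC1 dichotomization matches every planted
    archetype."""
    ct, truth = composition_from_truth(seed=seed)
    pa = pattern_pca(ct, ANCHORS)
    want = truth.patients.set_index("patient")["archetype"]
    assert (pa.group.reindex(want.index) == want).all()


def test_pattern_pca_invariances():
    ct, truth = composition_from_truth(seed=4)
    pa = pattern_pca(ct, ANCHORS)
    # patient-order permutation
    perm = ct.P.sample(frac=1.0, random_state=0).index
    ct_p = CompositionTable(P=ct.P.loc[perm], compartments=ct.compartments)
    pa_p = pattern_pca(ct_p, ANCHORS)
    assert (pa.group.loc[perm] == pa_p.group).all()
    # cluster-column permutation
    cols = ct.P.sample(frac=1.0, random_state=1, axis=1).columns
    ct_c = CompositionTable(P=ct.P[cols], compartments=ct.compartments.loc[cols])
    pa_c = pattern_pca(ct_c, ANCHORS)
    assert (pa.group == pa_c.group.reindex(pa.group.index)).all()


def test_identical_patients_get_identical_scores():
    ct, _ = composition_from_truth(seed=5)
    P = ct.P.copy()
    P.loc["P001"] = P.loc["P002"]
    ct2 = CompositionTable(P=P, compartments=ct.compartments)
    pa = pattern_pca(ct2, ANCHORS)
    assert pa.pattern_pc1.loc["P001"] == pytest.approx(pa.pattern_pc1.loc["P002"], abs=1e-9)


def test_missing_anchor_errors():
    ct, _ = composition_from_truth(seed=6)
    with pytest.raises(ValueError, match="NOPE"):
        pattern_pca(ct, {"CP2E": ["NOPE"], "N3MC": ["MyoF_normal_like"]})


def test_full_pipeline_pattern_recovery(small_cohort):
    """QC -> cluster -> annotate -> proportions -> pattern PCA recovers the
    planted archetypes on the shared 4-patient cohort."""
    cm, meta, truth = small_cohort
    res = recover_patterns(cm, meta, truth.reference_signatures(),
                           RunConfig(seed=0, min_pattern_patients=2))
    want = truth.patients.set_index("patient")["archetype"]
    assert (res.pattern.group.reindex(want.index) == want).all()


# ---------------------------------------------------------------------------
# correlation network
# ---------------------------------------------------------------------------

def test_concordant_pair_retained_anticorrelated_not():
    n = 10
    x = np.arange(n, dtype=float)
    P = pd.DataFrame({"up1": x, "up2": x * 2 + 1, "down": -x}, index=[f"P{i}" for i in range(n)])
    ct = CompositionTable(P=P, compartments=pd.Series("myeloid", index=P.columns))
    edges = correlation_network(ct)
    pairs = set(map(tuple, edges[["cluster_a", "cluster_b"]].to_numpy()))
    assert ("up1", "up2") in pairs
    assert all("down" not in p for p in pairs)  # rho = -1 is not retained
    assert edges.set_index(["cluster_a", "cluster_b"]).loc[("up1", "up2"), "rho"] == pytest.approx(1.0)


def test_spearman_p_matches_exhaustive_enumeration(rng):
    """n=7, no ties: the permutation p equals enumeration over all 7!
    orderings using the closed-form rho = 1 - 6*sum(d^2)/(n(n^2-1))."""
    x = rng.permutation(7).astype(float)
    y = (0.8 * x + rng.normal(0, 1.5, 7)).argsort().argsort().astype(float)
    rho_obs = stats.spearmanr(x, y).statistic
    rx = stats.rankdata(x)
    hits = total = 0
    for perm in permutations(stats.rankdata(y)):
        d = rx - np.array(perm)
        rho = 1 - 6 * (d**2).sum() / (7 * 48)
        total += 1
        hits += abs(rho) >= abs(rho_obs) - 1e-12
    expected = hits / total

    P = pd.DataFrame({"a": x, "b": y}, index=[f"P{i}" for i in range(7)])
    ct = CompositionTable(P=P + 1.0, compartments=pd.Series("m", index=P.columns))
    # run through the network op with thresholds that keep the pair
    edges = correlation_network(ct, rho_min=-2, p_max=1.1)
    got = edges.set_index(["cluster_a", "cluster_b"]).loc[("a", "b")]
    assert got["p"] == pytest.approx(expected, abs=1e-12)
    assert got["rho"] == pytest.approx(rho_obs, abs=1e-12)


def test_constant_column_skipped():
    P = pd.DataFrame(
        {"flat": np.ones(6), "var": np.arange(6.0), "var2": np.arange(6.0) ** 2},
        index=[f"P{i}" for i in range(6)],
    )
    ct = CompositionTable(P=P, compartments=pd.Series("m", index=P.columns))
    with pytest.warns(UserWarning, match="constant"):
        edges = correlation_network(ct)
    assert not any(edges["cluster_a"].eq("flat") | edges["cluster_b"].eq("flat"))


# ---------------------------------------------------------------------------
# pattern signatures
# ---------------------------------------------------------------------------

def sig(name, genes):
    return GeneSignature(name=name, genes=list(genes))


def test_assemble_union_and_disjointness():
    markers = {"c1": sig("c1", "AB"), "c2": sig("c2", "BC"), "c3": sig("c3", "D")}
    out = assemble_pattern_signatures(markers, {"X": ["c1", "c2"], "Y": ["c3"]})
    assert out["X"].genes == ["A", "B", "C"]
    assert out["Y"].genes == ["D"]


def test_shared_gene_removed_from_both():
    markers = {"c1": sig("c1", ["A", "S"]), "c2": sig("c2", ["B", "S"])}
    out = assemble_pattern_signatures(markers, {"X": ["c1"], "Y": ["c2"]})
    assert out["X"].genes == ["A"] and out["Y"].genes == ["B"]


def test_empty_union_errors():
    markers = {"c1": sig("c1", ["S"]), "c2": sig("c2", ["S"])}
    with pytest.raises(ValueError):
        assemble_pattern_signatures(markers, {"X": ["c1"], "Y": ["c2"]})


def test_pattern_signatures_contain_planted_markers():
    """Pattern signatures assembled from detected markers recover >= 80% of
    each member cell type's planted markers (needs a cohort large enough for
    every anchor cell type to form its own cluster)."""
    from tmepat.markers import find_markers, top_markers
    from tmepat.pipeline import cluster_cells

    cm, meta, truth = synthetic.simulate_sc_cohort(
        n_patients=6, cells_per_patient=450, seed=8
    )
    res = cluster_cells(cm, meta, truth.reference_signatures(), RunConfig(seed=0))
    df = find_markers(res.nm, res.assignment)
    sigs = top_markers(df, n=10, label_by=res.assignment.cluster_table["cell_type"])
    membership = {"N3MC": [c for c in synthetic.N3MC_ANCHORS if c in sigs],
                  "CP2E": [c for c in synthetic.CP2E_ANCHORS if c in sigs]}
    assert len(membership["N3MC"]) >= 4 and len(membership["CP2E"]) >= 3
    out = assemble_pattern_signatures({k: v for k, v in sigs.items()}, membership)
    for pattern in ("N3MC", "CP2E"):
        planted = {g for c in membership[pattern] for g in truth.signatures[c]}
        got = set(out[pattern].genes)
        assert len(got & planted) / len(planted) >= 0.8


def test_reduce_signature_exact_budget():
    markers = {
        "c1": sig("c1", [f"a{i}" for i in range(8)]),
        "c2": sig("c2", [f"b{i}" for i in range(8)]),
        "c3": sig("c3", [f"d{i}" for i in range(15)]),
    }
    membership = {"X": ["c1", "c2"], "Y": ["c3"]}
    full = assemble_pattern_signatures(markers, membership)
    red = reduce_signature(full, markers, membership, k_total=20)
    assert len(red["X"].genes) == 10 and len(red["Y"].genes) == 10
    # round-robin: X alternates c1, c2 top markers
    assert red["X"].genes[:4] == ["a0", "b0", "a1", "b1"]


def test_reduce_signature_minimal_budget():
    markers = {"c1": sig("c1", ["a0", "a1"]), "c2": sig("c2", ["b0"])}
    membership = {"X": ["c1"], "Y": ["c2"]}
    full = assemble_pattern_signatures(markers, membership)
    red = reduce_signature(full, markers, membership, k_total=2)
    assert red["X"].genes == ["a0"] and red["Y"].genes == ["b0"]


def test_reduce_signature_deterministic():
    markers = {
        "c1": sig("c1", [f"a{i}" for i in range(30)]),
        "c2": sig("c2", [f"b{i}" for i in range(30)]),
    }
    membership = {"X": ["c1"], "Y": ["c2"]}
    full = assemble_pattern_signatures(markers, membership)
    a = reduce_signature(full, markers, membership)
    b = reduce_signature(full, markers, membership)
    assert a["X"].genes == b["X"].genes and a["Y"].genes == b["Y"].genes
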