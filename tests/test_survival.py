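import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from tmepat import synthetic
from tmepat.core_io import GeneSignature
from tmepat.survival import (
    BulkCohort,
    cox_fit,
    km_curve,
    km_logrank,
    pattern_score,
    read_bulk_cohort,
    ssgsea,
    stratify_median,
)


def make_cohort(X, genes=None, time=None, event=None):
    n = X.shape[0]
    samples = [f"S{i}" for i in range(n)]
    time = time if time is not None else np.arange(1.0, n + 1)
    event = event if event is not None else np.ones(n, dtype=int)
    surv = pd.DataFrame({"time": time, "event": event}, index=samples)
    genes = genes or [f"G{j}" for j in range(X.shape[1])]
    return BulkCohort(samples=samples, genes=genes, X=np.asarray(X, float), survival=surv)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_oracle(x, in_set_mask, alpha):
    """Independent step-by-step running-sum enrichment score for one sample."""
    n = len(x)
    r = stats.rankdata(x)
    order = sorted(range(n), key=lambda i: (-r[i], i))
    w_total = sum(abs(r[i]) ** alpha for i in order if in_set_mask[i])
    n_out = n - sum(in_set_mask)
    cum_in = cum_out = 0.0
    es = 0.0
    for i in order:
        if in_set_mask[i]:
            cum_in += abs(r[i]) ** alpha / w_total
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def test_ssgsea_matches_running_sum_oracle(rng):
    """20-gene x 3-sample fixture equals the independent oracle to 1e-9."""
    X = rng.random((3, 20))
    X[1, 3] = X[1, 7]  # a tie
    bc = make_cohort(X)
    sig_genes = ["G2", "G5", "G7", "G11", "G19"]
    es = ssgsea(bc, [GeneSignature("s", sig_genes)], alpha=0.25, normalize=False)
    mask = [g in sig_genes for g in bc.genes]
    for s in range(3):
        want = ssgsea_oracle(X[s], mask, 0.25)
        assert es.ES.iloc[s, 0] == pytest.approx(want, abs=1e-9)


def test_identical_samples_identical_scores(rng):
    X = rng.random((4, 30))
    X[2] = X[0]
    bc = make_cohort(X)
    es = ssgsea(bc, [GeneSignature("s", ["G1", "G4", "G9"])])
    assert es.ES.iloc[2, 0] == pytest.approx(es.ES.iloc[0, 0], abs=1e-12)


def test_rank_preserving_transform_leaves_es_unchanged(rng):
    X = rng.random((3, 25))
    bc = make_cohort(X)
    sig = GeneSignature("s", ["G3", "G8", "G15"])
    a = ssgsea(bc, [sig], normalize=False)
    X2 = X.copy()
    X2[1] = np.exp(3 * X2[1])  # monotone transform of one sample
    b = ssgsea(make_cohort(X2), [sig], normalize=False)
    assert b.ES.iloc[1, 0] == pytest.approx(a.ES.iloc[1, 0], abs=1e-9)


def test_normalization_divides_by_global_range(rng):
    X = rng.random((5, 30))
    bc = make_cohort(X)
    sigs = [GeneSignature("a", ["G1", "G2"]), GeneSignature("b", ["G20", "G25"])]
    raw = ssgsea(bc, sigs, normalize=False).ES.to_numpy()
    norm = ssgsea(bc, sigs, normalize=True).ES.to_numpy()
    np.testing.assert_allclose(norm, raw / (raw.max() - raw.min()), atol=1e-12)


def test_empty_overlap_errors(rng):
    bc = make_cohort(rng.random((3, 10)))
    with pytest.raises(ValueError, match="nope"):
        ssgsea(bc, [GeneSignature("nope", ["ZZZ"])])


# ---------------------------------------------------------------------------
# pattern score + stratification
# ---------------------------------------------------------------------------

def test_pattern_score_modes(rng):
    X = rng.random((6, 30))
    bc = make_cohort(X)
    es = ssgsea(bc, [GeneSignature("p", ["G1", "G2"]), GeneSignature("n", ["G5", "G6"])])
    diff = pattern_score(es, "p", "n")
    np.testing.assert_allclose(diff.to_numpy(), (es.ES["p"] - es.ES["n"]).to_numpy())
    es.ES.loc[:, "n"] = -1.0
    with pytest.raises(ValueError, match="ratio"):
        pattern_score(es, "p", "n", mode="ratio")


def test_score_ordering_invariant_to_constant_shift(rng):
    X = rng.random((6, 30))
    bc = make_cohort(X)
    es = ssgsea(bc, [GeneSignature("p", ["G1", "G2"]), GeneSignature("n", ["G5", "G6"])])
    before = pattern_score(es, "p", "n").rank()
    es.ES += 5.0
    after = pattern_score(es, "p", "n").rank()
    pd.testing.assert_series_equal(before, after)


def test_stratify_median_ties_to_low():
    s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    g = stratify_median(s)
    assert g.tolist() == ["low", "low", "high", "high"]
    # odd n: the sample sitting exactly at the median goes low
    s2 = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    assert stratify_median(s2).loc["b"] == "low"


def test_stratify_all_identical_warns_all_low():
    s = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
    with pytest.warns(UserWarning):
        g = stratify_median(s)
    assert (g == "low").all()


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def test_km_no_events_curve_is_one():
    curve = km_curve(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
    assert (curve["survival"] == 1.0).all()


def test_km_no_censoring_equals_empirical_survival(rng):
    t = rng.exponential(1.0, 40)
    curve = km_curve(t, np.ones(40, dtype=int))
    for _, row in curve.iterrows():
        emp = (t > row["time"]).mean()
        assert row["survival"] == pytest.approx(emp, abs=1e-12)


def test_km_monotone_in_unit_interval(rng):
    t = rng.exponential(1.0, 60)
    e = rng.integers(0, 2, 60)
    if e.sum() == 0:
        e[0] = 1
    curve = km_curve(t, e)
    s = curve["survival"].to_numpy()
    assert ((s >= 0) & (s <= 1)).all()
    assert (np.diff(s) <= 1e-12).all()


def test_identical_groups_give_chi2_zero():
    X = np.zeros((8, 3))
    t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
    e = np.ones(8, dtype=int)
    bc = make_cohort(X, time=t, event=e)
    groups = pd.Series(list("AAAABBBB"), index=bc.samples)
    res = km_logrank(bc, groups)
    assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.logrank_p == pytest.approx(1.0, abs=1e-12)


def test_logrank_matches_hand_computed_hypergeometric_sum():
    """6 subjects, times 1..6, all events, groups ABABAB: chi2 equals the
    explicit O-E / hypergeometric-variance sum to 1e-10."""
    t = np.arange(1.0, 7.0)
    e = np.ones(6, dtype=int)
    g = np.array(list("ABABAB"))
    # hand computation: at each event time one death, risk sets shrink by one
    o_minus_e = 0.0
    v = 0.0
    for i, ti in enumerate(t):
        at_risk = 6 - i
        n_a = sum(1 for j in range(i, 6) if g[j] == "A")
        d = 1
        o = 1 if g[i] == "A" else 0
        e1 = n_a / at_risk
        o_minus_e += o - e1
        if at_risk > 1:
            v += (n_a / at_risk) * (1 - n_a / at_risk) * (at_risk - d) / (at_risk - 1)
    want = o_minus_e**2 / v

    bc = make_cohort(np.zeros((6, 2)), time=t, event=e)
    res = km_logrank(bc, pd.Series(g, index=bc.samples))
    assert res.logrank_chi2 == pytest.approx(want, abs=1e-10)


def test_logrank_symmetric_in_labels(rng):
    t = rng.exponential(1.0, 30)
    e = rng.integers(0, 2, 30)
    e[:5] = 1
    bc = make_cohort(np.zeros((30, 2)), time=t, event=e)
    g = pd.Series(rng.permutation(list("AB") * 15), index=bc.samples)
    flipped = g.map({"A": "B", "B": "A"})
    assert km_logrank(bc, g).logrank_chi2 == pytest.approx(
        km_logrank(bc, flipped).logrank_chi2, abs=1e-12
    )


def test_logrank_agrees_with_lifelines(rng):
    from lifelines.statistics import logrank_test

    t = rng.exponential(1.0, 50)
    e = rng.integers(0, 2, 50)
    e[:10] = 1
    g = rng.integers(0, 2, 50)
    bc = make_cohort(np.zeros((50, 2)), time=t, event=e)
    res = km_logrank(bc, pd.Series(np.where(g == 1, "A", "B"), index=bc.samples))
    ll = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
    assert res.logrank_chi2 == pytest.approx(ll.test_statistic, rel=1e-8)
    assert res.logrank_p == pytest.approx(ll.p_value, rel=1e-8)


def test_no_events_anywhere_errors():
    bc = make_cohort(np.zeros((4, 2)), time=np.arange(1.0, 5), event=np.zeros(4, dtype=int))
    with pytest.raises(ValueError, match="events"):
        km_logrank(bc, pd.Series(list("AABB"), index=bc.samples))


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def breslow_loglik(beta, t, e, x):
    """Independent direct evaluation of the Breslow log partial likelihood."""
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = np.flatnonzero(t >= t[i])
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def test_constant_covariate_errors():
    bc = make_cohort(np.zeros((5, 2)), time=np.arange(1.0, 6), event=np.ones(5, dtype=int))
    with pytest.raises(ValueError, match="constant"):
        cox_fit(bc, np.ones(5))


def test_cox_matches_independent_optimizer(rng):
    """No-ties fixture: Newton-Raphson beta equals a scalar maximization of
    an independently coded partial likelihood to 1e-6."""
    n = 40
    x = rng.normal(0, 1, n)
    t = rng.exponential(np.exp(-0.7 * x))
    t += np.linspace(0, 1e-6, n)  # guarantee no ties
    e = np.ones(n, dtype=int)
    bc = make_cohort(np.zeros((n, 2)), time=t, event=e)
    res = cox_fit(bc, x)
    opt = optimize.minimize_scalar(
        lambda b: -breslow_loglik(b, t, e, x), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    )
    assert res.cox_beta == pytest.approx(opt.x, abs=1e-6)


def test_cox_agrees_with_lifelines_without_ties(rng):
    from lifelines import CoxPHFitter

    n = 60
    x = rng.normal(0, 1, n)
    t = rng.exponential(np.exp(-0.5 * x)) + np.linspace(0, 1e-6, n)
    e = (rng.random(n) < 0.8).astype(int)
    if e.sum() == 0:
        e[0] = 1
    bc = make_cohort(np.zeros((n, 2)), time=t, event=e)
    res = cox_fit(bc, x)
    cph = CoxPHFitter().fit(
        pd.DataFrame({"T": t, "E": e, "x": x}), duration_col="T", event_col="E"
    )
    assert res.cox_beta == pytest.approx(cph.params_["x"], abs=1e-5)
    assert res.cox_se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)


def test_cox_recovers_true_log_hr():
    """Simulated exponential survival with true log-HR = ln 2: mean estimate
    over 20 replicates (n=500, no censoring) within +/-0.1."""
    betas = []
    for rep in range(20):
        bc, truth = synthetic.simulate_bulk_cohort(
            n_samples=500, survival_beta=np.log(2), censor_rate=0.0,
            seed=900 + rep, n_background_genes=20,
        )
        x = (truth.samples["archetype"] == "CP2E").astype(float)
        betas.append(cox_fit(bc, x).cox_beta)
    assert abs(np.mean(betas) - np.log(2)) <= 0.1


def test_cox_perfect_separation_errors():
    t = np.array([1.0, 2, 3, 10, 11, 12])
    e = np.ones(6, dtype=int)
    x = np.array([1.0, 1, 1, 0, 0, 0])  # all early deaths in one group
    bc = make_cohort(np.zeros((6, 2)), time=t, event=e)
    with pytest.raises(ValueError, match="separation"):
        cox_fit(bc, x)


def test_cox_hr_and_ci_consistent(rng):
    n = 80
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(np.exp(-0.6 * x))
    bc = make_cohort(np.zeros((n, 2)), time=t, event=np.ones(n, dtype=int))
    res = cox_fit(bc, x)
    assert res.hr == pytest.approx(np.exp(res.cox_beta))
    assert res.ci_low < res.hr < res.ci_high


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_bulk_cohort_drops_missing_genes(tmp_path):
    expr = pd.DataFrame(
        {"S1": [1.0, 2.0, np.nan], "S2": [2.0, 1.0, 3.0]},
        index=["G1", "G2", "G3"],
    )
    expr.to_csv(tmp_path / "expr.tsv", sep="\t")
    pd.DataFrame({"time": [5.0, 6.0], "event": [1, 0]}, index=["S1", "S2"]).to_csv(
        tmp_path / "surv.tsv", sep="\t"
    )
    bc = read_bulk_cohort(tmp_path / "expr.tsv", tmp_path / "surv.tsv")
    assert bc.genes == ["G1", "G2"]
    assert bc.X.shape == (2, 2)
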