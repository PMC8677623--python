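"""Bulk-cohort enrichment scoring and survival stratification.

Implements single-sample GSEA (rank-weighted running-sum enrichment, exponent
alpha = 0.25, optional global-range normalization), median dichotomization of
scores (ties to the low group), Kaplan-Meier curves, the two-group log-rank
test with hypergeometric variance, and univariate Cox proportional hazards
fitted by Newton-Raphson on the Breslow partial likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSignature

logger = logging.getLogger("tmepat")

__all__ = [
    "BulkCohort",
    "EnrichmentScores",
    "SurvivalResult",
    "read_bulk_cohort",
    "ssgsea",
    "pattern_score",
    "stratify_median",
    "km_curve",
    "km_logrank",
    "cox_fit",
]


@dataclass
class BulkCohort:
    """Sample x gene log-expression with survival (time > 0, event in {0, 1})."""

    samples: list[str]
    genes: list[str]
    X: np.ndarray  # samples x genes
    survival: pd.DataFrame  # index sample, columns time, event
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.samples), len(self.genes)):
            raise ValueError("X must be samples x genes")
        if self.survival is not None and len(self.survival):
            missing = set(self.samples) - set(self.survival.index)
            if missing:
                raise ValueError(f"survival table missing samples: {sorted(missing)[:5]}")
            if (self.survival["time"] <= 0).any():
                raise ValueError("survival times must be positive")


def read_bulk_cohort(expr_path: str | Path, survival_path: str | Path) -> BulkCohort:
    """Load a bulk cohort: genes-in-rows log-expression TSV (first column gene
    symbol, one column per sample) plus a (sample, time, event) survival TSV.
    Genes with any missing value are dropped with a note."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    n_bad = int(expr.isna().any(axis=1).sum())
    if n_bad:
        logger.info("read_bulk_cohort: dropping %d genes with missing values", n_bad)
        expr = expr.dropna(axis=0)
    surv = pd.read_csv(survival_path, sep="\t", index_col=0)
    return BulkCohort(
        samples=expr.columns.tolist(),
        genes=expr.index.tolist(),
        X=expr.to_numpy().T,
        survival=surv[["time", "event"]],
    )


@dataclass
class EnrichmentScores:
    ES: pd.DataFrame  # sample x signature
    alpha: float
    normalized: bool
    overlap: dict[str, int] = field(default_factory=dict)  # genes found per signature


def ssgsea(
    bc: BulkCohort,
    sigs: Sequence[GeneSignature],
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentScores:
    """Single-sample GSEA enrichment scores.

    Per sample, genes are ranked by expression (ties by average rank) and
    walked in decreasing order; in-set genes step the running sum up by their
    rank value raised to *alpha* (normalized by the in-set total), out-of-set
    genes step it down uniformly. The enrichment score is the sum of the
    running difference over all positions. With *normalize*, all scores are
    rescaled by the global (max - min) across the score matrix.
    """
    n_samples, n_genes = bc.X.shape
    lut = {g: i for i, g in enumerate(bc.genes)}
    memberships = []
    overlap = {}
    for sig in sigs:
        idx = np.array([lut[g] for g in sig.genes if g in lut], dtype=int)
        overlap[sig.name] = len(idx)
        if len(idx) == 0:
            raise ValueError(f"signature {sig.name!r} shares no genes with the cohort")
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        memberships.append(mask)

    ES = np.zeros((n_samples, len(sigs)))
    for s in range(n_samples):
        x = bc.X[s]
        r = stats.rankdata(x)  # ascending, average ties
        order = np.argsort(-r, kind="stable")  # decreasing expression
        r_sorted = r[order]
        for k, mask in enumerate(memberships):
            in_set = mask[order]
            n_in = in_set.sum()
            n_out = n_genes - n_in
            w = np.where(in_set, np.abs(r_sorted) ** alpha, 0.0)
            cdf_in = np.cumsum(w) / w.sum()
            cdf_out = np.cumsum(~in_set) / n_out
            ES[s, k] = float(np.sum(cdf_in - cdf_out))

    if normalize:
        span = ES.max() - ES.min()
        if span > 0:
            ES = ES / span
    df = pd.DataFrame(ES, index=bc.samples, columns=[s.name for s in sigs])
    return EnrichmentScores(ES=df, alpha=alpha, normalized=normalize, overlap=overlap)


def pattern_score(
    es: EnrichmentScores,
    pos: str,
    neg: str,
    mode: str = "difference",
) -> pd.Series:
    """Combine two signatures' enrichment scores per sample.

    ``difference`` (default): ES[pos] - ES[neg]. ``ratio``: ES[pos] / ES[neg],
    an error if any ES[neg] <= 0 (normalized scores can be non-positive,
    which is why difference is the default).
    """
    a, b = es.ES[pos], es.ES[neg]
    if mode == "difference":
        return (a - b).rename(f"{pos}-{neg}")
    if mode == "ratio":
        if (b <= 0).any():
            raise ValueError("ratio mode undefined: some ES[neg] <= 0")
        return (a / b).rename(f"{pos}/{neg}")
    raise ValueError(f"unknown mode {mode!r}")


def stratify_median(score: pd.Series) -> pd.Series:
    """Dichotomize at the median: high if score > median, low if <= median."""
    if len(score) < 2:
        raise ValueError("need >= 2 samples")
    med = float(score.median())
    if score.nunique() == 1:
        warnings.warn("all scores identical; every sample assigned to the low group")
    return pd.Series(np.where(score > med, "high", "low"), index=score.index, name="group")


@dataclass
class SurvivalResult:
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    cox_beta: float | None = None
    hr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    cox_se: float | None = None
    cox_p: float | None = None


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate (time, at_risk, events, survival)."""
    order = np.argsort(time, kind="stable")
    t, e = np.asarray(time, float)[order], np.asarray(event, int)[order]
    rows = []
    s = 1.0
    n = len(t)
    for ti in np.unique(t):
        at = ti == t
        at_risk = int((t >= ti).sum())
        d = int(e[at].sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append({"time": float(ti), "at_risk": at_risk, "events": d, "survival": s})
    return pd.DataFrame(rows)


def km_logrank(bc: BulkCohort, groups: pd.Series) -> SurvivalResult:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    chi2 = (sum O1 - sum E1)^2 / sum V with the hypergeometric variance at
    each distinct event time; p from chi-square with 1 df.
    """
    surv = bc.survival.loc[bc.samples]
    groups = groups.reindex(surv.index)
    levels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(levels) != 2 or any((groups == g).sum() == 0 for g in levels):
        raise ValueError("log-rank requires exactly two non-empty groups")
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events in either group; log-rank p undefined")

    res = SurvivalResult()
    g1 = (groups == levels[0]).to_numpy()
    for g in levels:
        m = (groups == g).to_numpy()
        res.km_curves[str(g)] = km_curve(time[m], event[m])

    o_minus_e = 0.0
    v_sum = 0.0
    for ti in np.unique(time[event == 1]):
        at_risk = time >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(event[(time == ti)].sum())
        d1 = int(event[(time == ti) & g1].sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            v_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v_sum <= 0:
        raise ValueError("log-rank variance is zero")
    res.logrank_chi2 = float(o_minus_e**2 / v_sum)
    res.logrank_p = float(stats.chi2.sf(res.logrank_chi2, df=1))
    return res


def _breslow_derivatives(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Log partial likelihood score and information under Breslow ties."""
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    eta = np.exp(beta * x)
    # reverse cumulative risk-set sums
    s0 = np.cumsum((eta)[::-1])[::-1]
    s1 = np.cumsum((x * eta)[::-1])[::-1]
    s2 = np.cumsum((x * x * eta)[::-1])[::-1]
    # map each position to the first index with the same time (risk set start)
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    U = 0.0
    I = 0.0
    ev = np.flatnonzero(e == 1)
    for i in ev:
        j = first[i]
        m1 = s1[j] / s0[j]
        U += x[i] - m1
        I += s2[j] / s0[j] - m1 * m1
    return U, I


def cox_fit(
    bc: BulkCohort,
    covariate: pd.Series | np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> SurvivalResult:
    """Univariate Cox proportional hazards (Breslow ties, Newton-Raphson).

    The covariate may be numeric or a two-level label series (the second
    sorted level is coded 1). Wald CI: exp(beta +/- 1.96 se). Monotone
    likelihood (perfect separation) raises an error; Firth-type corrections
    are out of scope.
    """
    surv = bc.survival.loc[bc.samples]
    if isinstance(covariate, pd.Series):
        covariate = covariate.reindex(surv.index)
        if covariate.dtype == object or str(covariate.dtype) == "category":
            levels = sorted(pd.unique(covariate.dropna()))
            if len(levels) != 2:
                raise ValueError("label covariate must have exactly two levels")
            covariate = (covariate == levels[1]).astype(float)
        x = covariate.to_numpy(float)
    else:
        x = np.asarray(covariate, float)
    t = surv["time"].to_numpy(float)
    e = surv["event"].to_numpy(int)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    beta = 0.0
    info = np.nan
    for _ in range(max_iter):
        U, info = _breslow_derivatives(beta, t, e, x)
        if info <= 0:
            raise ValueError("non-positive information; cannot fit")
        step = U / info
        beta += step
        if abs(beta) > 20:
            raise ValueError(
                "monotone partial likelihood (perfect separation); "
                "Firth-type handling is out of scope"
            )
        if abs(step) < tol:
            break

    se = float(1.0 / np.sqrt(info))
    z = beta / se
    res = SurvivalResult(
        cox_beta=float(beta),
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        cox_se=se,
        cox_p=float(2.0 * stats.norm.sf(abs(z))),
    )
    return res
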