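"""Proliferation metagene, concordance-based patient grouping, and survival
inference: Kaplan-Meier curves, the log-rank test, Cox regression (Efron tie
handling, via lifelines) and Fisher's exact composition tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import OmicsMatrix
from .synthetic_data import PROLIFERATION_GENES

DEFAULT_PROLIFERATION_GENES = list(PROLIFERATION_GENES)


@dataclass
class MetageneScore:
    scores: pd.Series
    genes_used: list[str]
    genes_missing: list[str]
    standardized: bool


@dataclass
class SurvivalFit:
    model: str                                   # km | logrank | cox
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    statistic: float = float("nan")              # log-rank chi-square
    df: int = 0
    p: float = float("nan")
    coefficients: pd.DataFrame | None = None     # cox: HR, CI, p per covariate

    def __post_init__(self) -> None:
        for g, curve in self.km_curves.items():
            s = curve["survival"].to_numpy()
            if (np.diff(s) > 1e-12).any():
                raise ValueError(f"KM survival not non-increasing for {g}")
        if self.coefficients is not None:
            c = self.coefficients
            if (c["hr"] <= 0).any():
                raise ValueError("HR must be positive")
            bad = (c["hr"] < c["ci_low"] - 1e-9) | (c["hr"] > c["ci_high"] + 1e-9)
            if bad.any():
                raise ValueError("CI does not contain HR")


@dataclass
class FisherResult:
    table: np.ndarray
    odds_ratio: float
    p: float

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")


# ---------------------------------------------------------------------------
# Proliferation metagene
# ---------------------------------------------------------------------------

def proliferation_score(mrna: OmicsMatrix,
                        gene_list: Sequence[str] | None = None,
                        standardize: bool = True) -> MetageneScore:
    """Per-sample sum of the listed genes' log2 values.

    With ``standardize`` (default) each gene is z-scored across samples before
    summing, making the score robust to per-gene scale.  Genes absent from
    the matrix are reported, not imputed.
    """
    genes = list(gene_list) if gene_list is not None \
        else DEFAULT_PROLIFERATION_GENES
    present = [g for g in genes if g in set(mrna.feature_ids)]
    missing = [g for g in genes if g not in set(mrna.feature_ids)]
    if not present:
        raise ValueError("none of the listed genes is on the mRNA matrix")
    vals = mrna.select_features(present).values
    if standardize:
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        vals = (vals - mean) / sd
    scores = pd.Series(np.nansum(vals, axis=0), index=mrna.sample_ids)
    return MetageneScore(scores, present, missing, standardize)


# ---------------------------------------------------------------------------
# Concordance-quantile patient groups
# ---------------------------------------------------------------------------

def concordance_groups(scores: pd.Series, lower_q: float = 0.25,
                       upper_q: float = 0.75) -> pd.Series:
    """Stratify samples into low / mid / high by empirical score quantiles.

    Quantiles use the linear-interpolation convention; scores strictly below
    the lower cut are "low", strictly above the upper cut are "high", and
    boundary ties land in "mid".
    """
    s = scores.dropna()
    if len(s) < 8:
        raise ValueError("need >= 8 scored samples")
    if s.nunique() == 1:
        raise ValueError("all scores identical; cannot stratify")
    lo = float(np.quantile(s.to_numpy(), lower_q))
    hi = float(np.quantile(s.to_numpy(), upper_q))
    out = pd.Series("mid", index=s.index, dtype=object)
    out[s < lo] = "low"
    out[s > hi] = "high"
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(times: Sequence[float], events: Sequence[int],
                groups: Sequence[str] | None = None) -> SurvivalFit:
    """Product-limit survival estimate per group with at-risk accounting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if groups is None:
        groups = np.array(["all"] * times.size)
    else:
        groups = np.asarray(groups, dtype=object)
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        t, e = times[mask], events[mask]
        uniq = np.unique(t)
        rows, surv = [], 1.0
        for u in uniq:
            at_risk = int((t >= u).sum())
            d = int(((t == u) & (e == 1)).sum())
            if d > 0:
                surv *= 1.0 - d / at_risk
            rows.append({"time": float(u), "at_risk": at_risk,
                         "events": d, "survival": surv})
        curves[str(g)] = pd.DataFrame(rows)
    return SurvivalFit("km", km_curves=curves)


def logrank_test(times: Sequence[float], events: Sequence[int],
                 groups: Sequence[str]) -> SurvivalFit:
    """k-group log-rank: observed minus expected chi-square over event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=object)
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if events.sum() == 0:
        raise ValueError("no events")
    event_times = np.unique(times[events == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for u in event_times:
        at_risk = times >= u
        n = int(at_risk.sum())
        d = int(((times == u) & (events == 1)).sum())
        ni = np.array([(at_risk & (groups == g)).sum() for g in labels],
                      dtype=float)
        di = np.array([((times == u) & (events == 1) & (groups == g)).sum()
                       for g in labels], dtype=float)
        obs += di
        exp += d * ni / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    var[a, b] += factor * ni[a] / n * (delta - ni[b] / n)
    z = (obs - exp)[:-1]
    vsub = var[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(vsub) @ z)
    p = float(stats.chi2.sf(chi2, k - 1))
    return SurvivalFit("logrank", statistic=chi2, df=k - 1, p=p)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def cox_fit(times: Sequence[float], events: Sequence[int],
            covariates: pd.DataFrame) -> SurvivalFit:
    """Cox proportional hazards with Efron tie handling (lifelines backend).

    ``covariates`` holds numeric columns (indicators, an ordinal trend code,
    or adjustment covariates).  Returns per-covariate HR, Wald 95% CI and p.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no events")
    cov = covariates.reset_index(drop=True).astype(float)
    for col in cov.columns:
        if cov[col].nunique() <= 1:
            raise ValueError(f"constant covariate: {col}")
    df = cov.copy()
    df["__time"] = times
    df["__event"] = events
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="__time", event_col="__event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    summ = fitter.summary
    coef = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci_low": summ["exp(coef) lower 95%"],
        "ci_high": summ["exp(coef) upper 95%"],
        "se": summ["se(coef)"],
        "p": summ["p"],
    })
    return SurvivalFit("cox", coefficients=coef)


def cox_trend(times: Sequence[float], events: Sequence[int],
              group_labels: Sequence[str],
              adjust: pd.DataFrame | None = None) -> SurvivalFit:
    """Cox trend across ordered low/mid/high groups (coded 0/1/2), optionally
    adjusted for additional covariates."""
    code = {"low": 0.0, "mid": 1.0, "high": 2.0}
    trend = pd.Series([code[g] for g in group_labels], name="trend")
    cov = pd.DataFrame({"trend": trend})
    if adjust is not None:
        for col in adjust.columns:
            cov[col] = np.asarray(adjust[col], dtype=float)
    return cox_fit(times, events, cov)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    p sums hypergeometric probabilities of tables at most as probable as the
    observed one.  The odds ratio is the sample OR, with a 0.5 continuity
    correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or \
            not np.array_equal(t, np.floor(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orx = (a * d) / (b * c)
    return FisherResult(np.asarray(table, dtype=int), float(orx), float(p))


def association_table(flags: Mapping[str, int],
                      samples_a: Sequence[str],
                      samples_b: Sequence[str]) -> np.ndarray:
    """Build the 2x2 (group x flag) count table for composition tests."""
    def counts(samples):
        pos = sum(1 for s in samples if flags.get(s, 0) == 1)
        return pos, len(samples) - pos
    a1, a0 = counts(samples_a)
    b1, b0 = counts(samples_b)
    return np.array([[a1, a0], [b1, b0]])
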