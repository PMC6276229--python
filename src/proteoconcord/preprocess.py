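"""Spectral-count filtering, normalization and differential abundance.

The processing order mirrors standard count-based workflows: a two-stage
feature filter (peptide support, then detection coverage), median-of-ratios
size factors, a shrunken log2 transform that stabilizes the variance of
low-count features, and per-feature negative-binomial Wald tests or paired
signed-rank tests, each followed by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import OmicsMatrix


@dataclass
class FilterReport:
    n_input_features: int
    n_removed_peptide_rule: int
    n_removed_coverage: int
    kept_feature_ids: list[str]

    def __post_init__(self) -> None:
        total = (len(self.kept_feature_ids) + self.n_removed_peptide_rule
                 + self.n_removed_coverage)
        if total != self.n_input_features:
            raise ValueError("filter report does not reconcile")


@dataclass
class SizeFactors:
    sample_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(self.factors)) or (self.factors <= 0).any():
            raise ValueError("size factors must be finite and positive")
        if len(self.sample_ids) != self.factors.size:
            raise ValueError("factor / sample length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, index=self.sample_ids)


@dataclass
class DifferentialResult:
    """Per-feature differential abundance table.

    ``table`` columns: log2_fc, stat, p, q, direction.  Features whose test is
    undefined carry NaN p/q and are excluded from the BH family.
    """

    table: pd.DataFrame
    method: str
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p, q = self.table["p"].to_numpy(), self.table["q"].to_numpy()
        ok = ~np.isnan(p)
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p outside [0, 1]")
        if (q[ok] + 1e-12 < p[ok]).any():
            raise ValueError("BH q must be >= p")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_features(counts: OmicsMatrix,
                    peptide_support: pd.Series | pd.DataFrame | None = None,
                    min_unique_peptides: int = 2,
                    min_coverage_fraction: float = 0.10,
                    ) -> tuple[OmicsMatrix, FilterReport]:
    """Apply the two-rule feature filter, in order.

    Rule 1 (skipped when ``peptide_support`` is absent): drop features whose
    unique-peptide support never reaches ``min_unique_peptides`` in any sample.
    ``peptide_support`` may be a per-feature Series (already maximized over
    samples) or a features x samples DataFrame.

    Rule 2: drop features detected (count > 0) in fewer than
    ``ceil(min_coverage_fraction * n_samples)`` samples.
    """
    if counts.value_kind != "counts":
        raise ValueError("filter_features expects a counts matrix")
    if not 0 < min_coverage_fraction <= 1:
        raise ValueError("min_coverage_fraction must be in (0, 1]")

    ids = np.array(counts.feature_ids)
    keep = np.ones(len(ids), dtype=bool)
    n_pep = 0
    if peptide_support is not None:
        if isinstance(peptide_support, pd.DataFrame):
            support = peptide_support.max(axis=1)
        else:
            support = peptide_support
        support = support.reindex(ids).fillna(0).to_numpy(dtype=float)
        keep = support >= min_unique_peptides
        n_pep = int((~keep).sum())

    n_samples = len(counts.sample_ids)
    min_detected = math.ceil(min_coverage_fraction * n_samples)
    detected = (counts.values > 0).sum(axis=1)
    coverage_fail = keep & (detected < min_detected)
    n_cov = int(coverage_fail.sum())
    keep = keep & ~coverage_fail

    kept_ids = [str(i) for i in ids[keep]]
    if not kept_ids:
        raise ValueError(
            "all features removed by filtering; relax min_unique_peptides "
            "or min_coverage_fraction")
    filtered = counts.select_features(kept_ids)
    report = FilterReport(len(ids), n_pep, n_cov, kept_ids)
    return filtered, report


# ---------------------------------------------------------------------------
# Normalization / transformation
# ---------------------------------------------------------------------------

def size_factors(counts: OmicsMatrix) -> SizeFactors:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over features (restricted to
    features positive in every sample) of count / geometric-mean(count).
    """
    if counts.value_kind != "counts":
        raise ValueError("size_factors expects a counts matrix")
    v = counts.values
    if v.shape[1] < 2:
        raise ValueError("size_factors needs at least 2 samples")
    allpos = (v > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no feature has positive counts in every sample")
    sub = v[allpos, :]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(list(counts.sample_ids), factors)


def rlog_like(counts: OmicsMatrix, factors: SizeFactors,
              prior_strength: float = 5.0) -> OmicsMatrix:
    """Shrunken log2 transform of size-factor-normalized counts.

    y_gs = w_gs * log2(q_gs + 0.5) + (1 - w_gs) * log2(mean_g + 0.5) with
    q_gs the normalized count, mean_g its across-sample mean, and
    w_gs = mean_g / (mean_g + prior_strength).  Low-mean features are pulled
    toward their own mean, which removes the inflation of across-sample
    variance at small counts; as prior_strength -> 0 this reduces to a plain
    log2(q + 0.5).
    """
    if prior_strength <= 0:
        raise ValueError("prior_strength must be positive")
    if counts.value_kind != "counts":
        raise ValueError("rlog_like expects a counts matrix")
    q = counts.values / factors.as_series().reindex(counts.sample_ids).to_numpy()
    mean_g = q.mean(axis=1)
    w = (mean_g / (mean_g + prior_strength))[:, None]
    y = w * np.log2(q + 0.5) + (1.0 - w) * np.log2(mean_g + 0.5)[:, None]
    return OmicsMatrix(list(counts.feature_ids), list(counts.sample_ids),
                       y, "transformed")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are passed through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return q
    psub = p[ok]
    order = np.argsort(psub, kind="mergesort")
    ranked = psub[order] * m / np.arange(1, m + 1)
    qsub = np.minimum.accumulate(ranked[::-1])[::-1]
    qsub = np.minimum(qsub, 1.0)
    out = np.empty(m)
    out[order] = qsub
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# Negative-binomial Wald test
# ---------------------------------------------------------------------------

def _dispersion_estimates(v: np.ndarray, factors: np.ndarray,
                          groups: np.ndarray) -> np.ndarray:
    """Per-feature NB dispersion: method of moments on normalized counts,
    shrunk (weight 0.5, log scale) toward a log-linear mean-dispersion trend.
    """
    q = v / factors[None, :]
    floor = 1e-8
    resid_var = np.zeros(v.shape[0])
    mean_all = q.mean(axis=1)
    dof = 0
    for g in np.unique(groups):
        cols = groups == g
        n = int(cols.sum())
        if n < 2:
            continue
        mg = q[:, cols].mean(axis=1)
        resid_var += ((q[:, cols] - mg[:, None]) ** 2).sum(axis=1)
        dof += n - 1
    var = resid_var / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean_all) / np.maximum(mean_all, 1e-12) ** 2
    raw = np.where(np.isfinite(raw), raw, floor)
    raw = np.maximum(raw, floor)

    # log-linear trend alpha ~ a * mean^b fitted on informative features
    inform = (mean_all > 0) & (raw > floor * 10)
    if inform.sum() >= 10:
        x = np.log(mean_all[inform])
        y = np.log(raw[inform])
        b, a = np.polyfit(x, y, 1)
        trend = np.exp(a + b * np.log(np.maximum(mean_all, 1e-12)))
        trend = np.maximum(trend, floor)
    else:
        trend = np.full_like(raw, np.exp(np.mean(np.log(raw))))
    shrunk = np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))
    return np.maximum(shrunk, floor)


def nb_wald(counts: OmicsMatrix, factors: SizeFactors,
            groups: pd.Series | dict,
            min_mean_for_bh: float = 1.0) -> DifferentialResult:
    """Per-feature NB log-linear model with a tumor/normal coefficient.

    The model is log mu_gs = b0_g + b1_g * [s is tumor] + log(factor_s); b1 is
    the log2-scale fold change after conversion.  Dispersion is estimated by
    method of moments with trend shrinkage and held fixed during a vectorized
    Newton-Raphson fit.  Wald z = b1 / SE, two-sided normal p, BH q over
    features whose mean normalized count is >= ``min_mean_for_bh``
    (independent-filtering surrogate).
    """
    if counts.value_kind != "counts":
        raise ValueError("nb_wald expects a counts matrix")
    g = pd.Series(groups).reindex(counts.sample_ids)
    if g.isna().any():
        raise ValueError("groups missing for some samples")
    x = (g == "tumor").to_numpy(dtype=float)
    if x.sum() == 0 or x.sum() == len(x):
        raise ValueError("both groups must be non-empty")

    v = counts.values
    f = factors.as_series().reindex(counts.sample_ids).to_numpy()
    alpha = _dispersion_estimates(v, f, g.to_numpy())

    q = v / f[None, :]
    testable = ~((v.sum(axis=1) == 0))
    n_t, n_n = x.sum(), (1 - x).sum()
    mean_t = (q * x[None, :]).sum(axis=1) / n_t
    mean_n = (q * (1 - x)[None, :]).sum(axis=1) / n_n
    # initialization with pseudocounts keeps logs finite
    b0 = np.log(np.maximum(mean_n, 0.0) + 0.1)
    b1 = np.log((mean_t + 0.1) / (mean_n + 0.1))

    a = alpha[:, None]
    for _ in range(50):
        mu = np.exp(b0[:, None] + b1[:, None] * x[None, :]) * f[None, :]
        w = mu / (1.0 + a * mu)          # Fisher weights
        r = (v - mu) / (1.0 + a * mu)    # score contributions
        s0 = r.sum(axis=1)
        s1 = (r * x[None, :]).sum(axis=1)
        i00 = w.sum(axis=1)
        i01 = (w * x[None, :]).sum(axis=1)
        i11 = i01
        det = i00 * i11 - i01 * i01
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (i00 * s1 - i01 * s0) / det
        d0 = np.clip(np.nan_to_num(d0), -2, 2)
        d1 = np.clip(np.nan_to_num(d1), -2, 2)
        b0 = b0 + d0
        b1 = b1 + d1
        if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < 1e-10:
            break

    mu = np.exp(b0[:, None] + b1[:, None] * x[None, :]) * f[None, :]
    w = mu / (1.0 + a * mu)
    i00 = w.sum(axis=1)
    i01 = (w * x[None, :]).sum(axis=1)
    det = i00 * i01 - i01 * i01
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = i00 / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    z = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~testable] = np.nan

    mean_all = q.mean(axis=1)
    in_family = testable & (mean_all >= min_mean_for_bh)
    p_bh = np.where(in_family, p, np.nan)
    qvals = bh_adjust(p_bh)

    log2_fc = b1 / np.log(2.0)
    table = pd.DataFrame({
        "log2_fc": log2_fc,
        "stat": z,
        "p": p,
        "q": qvals,
        "direction": np.where(log2_fc > 0, "up", "down"),
    }, index=counts.feature_ids)
    table.loc[~testable, ["log2_fc", "stat", "direction"]] = [np.nan, np.nan, ""]
    return DifferentialResult(table, "nb_wald",
                              notes={"min_mean_for_bh": min_mean_for_bh,
                                     "n_in_bh_family": int(in_family.sum())})


# ---------------------------------------------------------------------------
# Signed-rank tests
# ---------------------------------------------------------------------------

def signed_rank_test(differences: np.ndarray,
                     exact_max_n: int = 12) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped.  W is the positive-rank sum with midranks for tied
    magnitudes.  For n <= ``exact_max_n`` the two-sided p is computed by
    enumerating all 2^n sign patterns (valid under ties); otherwise a normal
    approximation with tie correction and continuity correction is used.
    Returns (W, p); (nan, nan) when every difference is zero.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return float("nan"), float("nan")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)
        w_null = signs @ ranks
        p_ge = np.mean(w_null >= w_pos - 1e-12)
        p_le = np.mean(w_null <= w_pos + 1e-12)
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        mu = n * (n + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - \
            np.sum(tie_sizes ** 3 - tie_sizes) / 48.0
        if var <= 0:
            return w_pos, float("nan")
        z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        p = min(1.0, p)
    return w_pos, float(p)


def paired_signed_rank(values: OmicsMatrix,
                       pairs: list[tuple[str, str]]) -> DifferentialResult:
    """Per-feature Wilcoxon signed-rank on tumor - normal paired differences.

    ``pairs`` lists (tumor_sample, normal_sample) ids; at least 6 complete
    pairs are required.  Reports the median paired difference as log2_fc
    (values are already on a log2-like scale).
    """
    usable = [(t, n) for t, n in pairs
              if t in values.sample_ids and n in values.sample_ids]
    if len(usable) < 6:
        raise ValueError(f"need >= 6 complete pairs, got {len(usable)}")
    ti = values.sample_index([t for t, _ in usable])
    ni = values.sample_index([n for _, n in usable])
    diffs = values.values[:, ti] - values.values[:, ni]

    stats_w = np.full(diffs.shape[0], np.nan)
    pvals = np.full(diffs.shape[0], np.nan)
    med = np.nanmedian(diffs, axis=1)
    for i in range(diffs.shape[0]):
        w, p = signed_rank_test(diffs[i])
        stats_w[i], pvals[i] = w, p
    qvals = bh_adjust(pvals)
    table = pd.DataFrame({
        "log2_fc": med,
        "stat": stats_w,
        "p": pvals,
        "q": qvals,
        "direction": np.where(med > 0, "up", np.where(med < 0, "down", "")),
    }, index=values.feature_ids)
    return DifferentialResult(table, "paired_signed_rank",
                              notes={"n_pairs": len(usable)})
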