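"""Within-sample and across-subject protein-mRNA Spearman concordance.

The per-sample "global" concordance is the tie-corrected Spearman correlation,
across matched protein-gene pairs, between one sample's protein vector and its
mRNA vector.  Across-subject concordance is the per-pair correlation across
the samples of a tissue group.  Group contrasts use rank-based tests
(rank-sum for two groups, Kruskal-Wallis for more).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import OmicsMatrix, PairMap

MIN_PAIRS = 30  # rank correlations on fewer pairs are too unstable to compare


@dataclass
class PairSet:
    pairs: list[tuple[str, str]]
    group: str

    def __post_init__(self) -> None:
        prot = [p for p, _ in self.pairs]
        if len(set(prot)) != len(prot):
            raise ValueError("duplicate protein_id in pair set")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def protein_ids(self) -> list[str]:
        return [p for p, _ in self.pairs]

    @property
    def gene_ids(self) -> list[str]:
        return [g for _, g in self.pairs]


@dataclass
class ConcordanceResult:
    """mode "within_sample": one rho per sample; "across_subject": one per pair."""

    mode: str
    scores: pd.Series            # index: sample_id or "protein|gene" pair key
    n_used: pd.Series            # pairs (within) or samples (across) per score
    group_labels: pd.Series | None = None
    na_reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("within_sample", "across_subject"):
            raise ValueError(f"unknown mode {self.mode!r}")
        vals = self.scores.dropna()
        if ((vals < -1 - 1e-12) | (vals > 1 + 1e-12)).any():
            raise ValueError("rho outside [-1, 1]")
        for key in self.scores.index[self.scores.isna()]:
            if key not in self.na_reasons:
                raise ValueError(f"NA score for {key} without a reason")


@dataclass
class GroupComparison:
    statistic: float
    p: float
    test: str
    group_sizes: dict[str, int]
    group_means: dict[str, float]
    group_medians: dict[str, float]

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or math.isnan(self.p)):
            raise ValueError("p outside [0, 1]")


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Spearman rho: Pearson correlation of midranks.

    Returns NaN for constant input or length < 3 (callers record the reason).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def _rho_matrix_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise tie-corrected Spearman between two equal-shape matrices."""
    ra = stats.rankdata(a, axis=0)
    rb = stats.rankdata(b, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    num = (ra * rb).sum(axis=0)
    den = np.sqrt((ra ** 2).sum(axis=0) * (rb ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


# ---------------------------------------------------------------------------
# Pair sets
# ---------------------------------------------------------------------------

def build_pair_set(protein_counts: OmicsMatrix, mrna: OmicsMatrix,
                   pairmap: PairMap, group_samples: Sequence[str],
                   group: str = "",
                   min_coverage_fraction: float = 0.10) -> PairSet:
    """Pairs whose protein passes the within-group detection-coverage filter
    and whose gene is present on the mRNA matrix; sorted by protein_id."""
    sub = protein_counts.select_samples(list(group_samples))
    min_detected = math.ceil(min_coverage_fraction * len(group_samples))
    detected = (sub.values > 0).sum(axis=1)
    passing = {f for f, d in zip(sub.feature_ids, detected) if d >= min_detected}
    genes = set(mrna.feature_ids)
    pairs = sorted((p, g) for p, g in pairmap.pairs
                   if p in passing and g in genes)
    if not pairs:
        raise ValueError("empty pair set after filtering")
    return PairSet(pairs, group)


# ---------------------------------------------------------------------------
# Concordance scores
# ---------------------------------------------------------------------------

def within_sample_concordance(protein_transformed: OmicsMatrix,
                              mrna: OmicsMatrix, pair_set: PairSet,
                              samples: Sequence[str],
                              group_labels: Mapping[str, str] | None = None,
                              ) -> ConcordanceResult:
    """Per-sample global rho over the pair set.

    Pairs with missing mRNA for a sample are dropped for that sample's score
    (pairwise-complete).  Scores on < MIN_PAIRS pairs are NA with a reason.
    """
    prot = protein_transformed.select_features(pair_set.protein_ids)
    rna = mrna.select_features(pair_set.gene_ids)
    scores, n_used, reasons = {}, {}, {}
    pi = prot.sample_index(list(samples))
    ri = rna.sample_index(list(samples))
    for s, ip, ir in zip(samples, pi, ri):
        x = prot.values[:, ip]
        y = rna.values[:, ir]
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        n_used[s] = n
        if n < MIN_PAIRS:
            scores[s] = np.nan
            reasons[s] = f"insufficient pairs ({n} < {MIN_PAIRS})"
            continue
        rho = spearman(x[ok], y[ok])
        scores[s] = rho
        if np.isnan(rho):
            reasons[s] = "constant vector"
    labels = None
    if group_labels is not None:
        labels = pd.Series({s: group_labels[s] for s in samples})
    return ConcordanceResult("within_sample", pd.Series(scores),
                             pd.Series(n_used), labels, reasons)


def per_pair_concordance(protein_transformed: OmicsMatrix,
                         mrna: OmicsMatrix, pair_set: PairSet,
                         samples: Sequence[str]) -> ConcordanceResult:
    """Per-pair rho across the samples of a group (>= 10 samples)."""
    if len(samples) < 10:
        raise ValueError("per-pair concordance needs >= 10 samples")
    prot = protein_transformed.select_features(pair_set.protein_ids)
    rna = mrna.select_features(pair_set.gene_ids)
    a = prot.select_samples(list(samples)).values.T   # samples x pairs
    b = rna.select_samples(list(samples)).values.T
    keys = [f"{p}|{g}" for p, g in pair_set.pairs]
    scores, n_used, reasons = {}, {}, {}
    complete = ~(np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0))
    rho_all = np.full(len(keys), np.nan)
    if complete.any():
        rho_all[complete] = _rho_matrix_columns(a[:, complete], b[:, complete])
    for j, key in enumerate(keys):
        if not complete[j]:
            x, y = a[:, j], b[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            rho = spearman(x[ok], y[ok]) if ok.sum() >= 3 else float("nan")
            n_used[key] = int(ok.sum())
            scores[key] = rho
            if np.isnan(rho):
                reasons[key] = "constant vector or insufficient samples"
            continue
        n_used[key] = len(samples)
        scores[key] = rho_all[j]
        if np.isnan(rho_all[j]):
            reasons[key] = "constant vector"
    return ConcordanceResult("across_subject", pd.Series(scores),
                             pd.Series(n_used), None, reasons)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def rank_sum_test(x: np.ndarray, y: np.ndarray,
                  exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null when both groups have n <= ``exact_max_n`` and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_concordance(result: ConcordanceResult,
                        labels: Mapping[str, str] | pd.Series,
                        ) -> GroupComparison:
    """Rank-based comparison of concordance scores across groups.

    Two groups: two-sided Wilcoxon rank-sum.  More: Kruskal-Wallis.  Group
    membership comes from ``labels`` keyed like the result's scores.
    """
    labels = pd.Series(labels)
    scores = result.scores
    groups: dict[str, np.ndarray] = {}
    for g in sorted(labels.dropna().unique()):
        keys = labels.index[labels == g]
        vals = scores.reindex(keys).dropna().to_numpy()
        if len(keys) > 0 and vals.size == 0:
            raise ValueError(f"group {g!r} has only NA scores")
        if vals.size:
            groups[g] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    arrays = list(groups.values())
    if len(arrays) == 2:
        stat, p = rank_sum_test(arrays[0], arrays[1])
        test = "wilcoxon_rank_sum"
    else:
        stat, p = stats.kruskal(*arrays)
        test = "kruskal_wallis"
    return GroupComparison(
        float(stat), float(p), test,
        {g: int(v.size) for g, v in groups.items()},
        {g: float(np.mean(v)) for g, v in groups.items()},
        {g: float(np.median(v)) for g, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# Robustness stratifications
# ---------------------------------------------------------------------------

def stratified_concordance(protein_transformed: OmicsMatrix,
                           mrna: OmicsMatrix, pair_set: PairSet,
                           samples: Sequence[str],
                           pair_labels: Mapping[str, str] | None = None,
                           exclude: Sequence[str] | None = None,
                           abundance_bins: int | None = None,
                           coverage_bins: int | None = None,
                           protein_counts: OmicsMatrix | None = None,
                           ) -> dict[str, ConcordanceResult]:
    """Within-sample concordance recomputed per pair stratum.

    Exactly one of ``pair_labels`` (label per protein_id), ``exclude``
    (protein ids to drop), ``abundance_bins`` (quantile bins of mean
    transformed abundance, default sextiles) or ``coverage_bins`` (quantile
    bins of detection fraction; requires ``protein_counts``) may be given;
    none at all reproduces the unstratified result under key "all".
    """
    chosen = [v is not None for v in
              (pair_labels, exclude, abundance_bins, coverage_bins)]
    if sum(chosen) > 1:
        raise ValueError("choose at most one stratification")

    def run(pairs: list[tuple[str, str]]) -> ConcordanceResult:
        return within_sample_concordance(
            protein_transformed, mrna, PairSet(pairs, pair_set.group), samples)

    if exclude is not None:
        drop = set(exclude)
        kept = [(p, g) for p, g in pair_set.pairs if p not in drop]
        return {"retained": run(kept)}
    if pair_labels is not None:
        out = {}
        for lab in sorted(set(pair_labels.values())):
            pairs = [(p, g) for p, g in pair_set.pairs
                     if pair_labels.get(p) == lab]
            out[str(lab)] = run(pairs) if len(pairs) >= MIN_PAIRS else \
                ConcordanceResult("within_sample",
                                  pd.Series(dtype=float), pd.Series(dtype=int))
        return out
    if abundance_bins is not None or coverage_bins is not None:
        if abundance_bins is not None:
            prot = protein_transformed.select_features(pair_set.protein_ids)
            metric = prot.select_samples(list(samples)).values.mean(axis=1)
            k, tag = abundance_bins, "abundance"
        else:
            if protein_counts is None:
                raise ValueError("coverage stratification needs protein_counts")
            prot = protein_counts.select_features(pair_set.protein_ids)
            sub = prot.select_samples(list(samples))
            metric = (sub.values > 0).mean(axis=1)
            k, tag = coverage_bins, "coverage"
        edges = np.quantile(metric, np.linspace(0, 1, k + 1))
        bins = np.clip(np.searchsorted(edges, metric, side="right") - 1, 0, k - 1)
        out = {}
        for b in range(k):
            pairs = [pair for pair, ib in zip(pair_set.pairs, bins) if ib == b]
            out[f"{tag}_bin_{b + 1}"] = run(pairs) if len(pairs) >= MIN_PAIRS \
                else ConcordanceResult("within_sample",
                                       pd.Series(dtype=float),
                                       pd.Series(dtype=int))
        return out
    return {"all": run(list(pair_set.pairs))}


def subset_robustness(protein_transformed: OmicsMatrix, mrna: OmicsMatrix,
                      pair_set: PairSet, samples: Sequence[str],
                      fraction: float, n_reps: int, seed: int,
                      ) -> pd.DataFrame:
    """Mean within-sample rho over random pair subsets.

    Returns one row per repetition with the subset's mean rho; fraction 1.0
    reproduces the full-set value in every repetition.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(round(fraction * len(pair_set)))
    if k < MIN_PAIRS:
        raise ValueError(f"subset size {k} < {MIN_PAIRS}")
    rng = np.random.default_rng(seed)
    rows = []
    pairs = list(pair_set.pairs)
    for rep in range(n_reps):
        idx = rng.choice(len(pairs), size=k, replace=False)
        sub = PairSet([pairs[i] for i in sorted(idx)], pair_set.group)
        res = within_sample_concordance(protein_transformed, mrna, sub, samples)
        rows.append({"rep": rep, "mean_rho": float(res.scores.mean()),
                     "n_pairs": k})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariate-adjusted association
# ---------------------------------------------------------------------------

def adjusted_association(response: pd.Series, predictor: pd.Series,
                         covariates: pd.DataFrame | None = None,
                         ) -> dict:
    """OLS of response on predictor plus covariates, and the partial
    correlation of the covariate-residualized variables.

    Categorical covariates are expanded to indicator columns (first level
    dropped).  Raises on collinear covariates, naming the aliased column.
    """
    df = pd.DataFrame({"__resp": response, "__pred": predictor})
    design_cols: list[tuple[str, pd.Series]] = []
    if covariates is not None:
        cov = covariates.copy()
        for col in cov.columns:
            s = cov[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                levels = sorted(s.dropna().unique())
                for lev in levels[1:]:
                    design_cols.append((f"{col}[{lev}]",
                                        (s == lev).astype(float)))
                df[col] = s  # keep for complete-case masking
            else:
                design_cols.append((col, s.astype(float)))
    for name, s in design_cols:
        df[f"__X_{name}"] = s
    df = df.dropna()
    n = len(df)
    p_cov = len(design_cols)
    if n < p_cov + 3:
        raise ValueError(f"too few complete cases ({n}) for {p_cov} covariates")

    y = df["__resp"].to_numpy(dtype=float)
    x = df["__pred"].to_numpy(dtype=float)
    C = np.column_stack([np.ones(n)] +
                        [df[f"__X_{name}"].to_numpy(dtype=float)
                         for name, _ in design_cols])
    # collinearity check on the covariate design
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        for j, (name, _) in enumerate(design_cols, start=1):
            reduced = np.delete(C, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"collinear covariate: {name}")
        raise ValueError("collinear covariates")

    X = np.column_stack([C, x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * xtx_inv[-1, -1])
    coef = float(beta[-1])
    t = coef / se if se > 0 else float("nan")
    p = 2.0 * stats.t.sf(abs(t), dof)

    # partial correlation: residualize both variables on the covariates
    proj = C @ np.linalg.lstsq(C, np.column_stack([y, x]), rcond=None)[0]
    ry = y - proj[:, 0]
    rx = x - proj[:, 1]
    denom = math.sqrt(float(ry @ ry) * float(rx @ rx))
    partial_r = float(ry @ rx) / denom if denom > 0 else float("nan")
    return {"coefficient": coef, "se": se, "t": float(t), "p": float(p),
            "partial_correlation": partial_r, "n": n}


# ---------------------------------------------------------------------------
# Cohort-level convenience pipeline
# ---------------------------------------------------------------------------

def score_cohort(cohort, prior_strength: float = 5.0,
                 min_coverage_fraction: float = 0.10) -> ConcordanceResult:
    """Full within-sample scoring path used by recovery tests and the CLI.

    Filters the protein counts at the overall coverage threshold, computes
    size factors and the shrunken log2 transform, builds the tumor and normal
    pair sets with group-level coverage, and scores every sample; group labels
    ("tumor"/"normal") are attached to the result.
    """
    from . import preprocess

    filtered, _ = preprocess.filter_features(
        cohort.protein, min_coverage_fraction=min_coverage_fraction)
    sf = preprocess.size_factors(filtered)
    rlog = preprocess.rlog_like(filtered, sf, prior_strength)
    all_scores, all_n, all_labels, reasons = {}, {}, {}, {}
    for tissue in ("tumor", "normal"):
        group_samples = cohort.samples.samples_with_tissue(tissue)
        if not group_samples:
            continue
        ps = build_pair_set(filtered, cohort.mrna, cohort.pairmap,
                            group_samples, group=tissue,
                            min_coverage_fraction=min_coverage_fraction)
        res = within_sample_concordance(rlog, cohort.mrna, ps, group_samples)
        for s in group_samples:
            all_scores[s] = res.scores[s]
            all_n[s] = res.n_used[s]
            all_labels[s] = tissue
            if s in res.na_reasons:
                reasons[s] = res.na_reasons[s]
    return ConcordanceResult("within_sample", pd.Series(all_scores),
                             pd.Series(all_n), pd.Series(all_labels), reasons)
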