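"""Pre-ranked enrichment (weighted Kolmogorov-Smirnov running sum) and
two-sample KS enrichment of gene sets in per-pair concordance values."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import GeneSetCollection
from .preprocess import bh_adjust
from .concordance import ConcordanceResult


@dataclass
class EnrichmentResult:
    """One row per gene set: score (ES/NES or signed KS D), raw p, BH q."""

    table: pd.DataFrame
    mode: str
    leading_edges: dict[str, list[str]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "es" in self.table.columns:
            es = self.table["es"].dropna()
            if (es.abs() > 1 + 1e-9).any():
                raise ValueError("|ES| must be <= 1")
        p, q = self.table["p"].to_numpy(), self.table["q"].to_numpy()
        ok = ~np.isnan(p)
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p outside [0, 1]")
        if (q[ok] + 1e-12 < p[ok]).any():
            raise ValueError("q must be >= p")


# ---------------------------------------------------------------------------
# Pre-ranked running-sum score
# ---------------------------------------------------------------------------

def _es_from_positions(positions: np.ndarray, stats_ranked: np.ndarray,
                       n: int, weight_p: float) -> tuple[float, int]:
    """ES and its position given sorted 0-based hit positions.

    Hits add |stat|^weight_p normalized by the set total; misses subtract
    1/(N - k).  The running sum is evaluated just before and just after each
    hit; the extremum of largest magnitude is the ES.
    """
    k = positions.size
    weights = np.abs(stats_ranked[positions]) ** weight_p
    total = weights.sum()
    if total == 0:          # all member stats are exactly zero
        weights = np.ones(k)
        total = float(k)
    hit_cum = np.cumsum(weights) / total
    if n == k:              # degenerate: no misses; ES = largest increment
        j = int(np.argmax(weights))
        return float(weights[j] / total), int(positions[j])
    pen = 1.0 / (n - k)
    misses_through = positions + 1 - np.arange(1, k + 1)   # misses at or before
    after = hit_cum - misses_through * pen
    before = np.concatenate([[0.0], hit_cum[:-1]]) - \
        (positions - np.arange(k)) * pen
    candidates = np.concatenate([after, before])
    j = int(np.argmax(np.abs(candidates)))
    es = float(candidates[j])
    pos = int(positions[j % k])
    return es, pos


def preranked_es(ranked: pd.Series, set_members: list[str],
                 weight_p: float = 1.0) -> tuple[float, list[str]]:
    """Weighted-KS enrichment score over a descending-sorted statistic.

    ``ranked`` maps feature -> statistic and must already be sorted in
    descending order with unique index.  Returns (ES, leading_edge): members
    at or before the ES position for positive ES, at or after for negative.
    """
    if ranked.index.duplicated().any():
        raise ValueError("duplicate features in ranking")
    idx_of = {f: i for i, f in enumerate(ranked.index)}
    positions = np.array(sorted(idx_of[m] for m in set_members if m in idx_of))
    if positions.size == 0:
        raise ValueError("set has no overlap with the ranking")
    stats_arr = ranked.to_numpy(dtype=float)
    es, pos = _es_from_positions(positions, stats_arr, len(ranked), weight_p)
    if es >= 0:
        lead = [ranked.index[i] for i in positions if i <= pos]
    else:
        lead = [ranked.index[i] for i in positions if i >= pos]
    return es, lead


def preranked_enrichment(ranked: pd.Series, collection: GeneSetCollection,
                         n_perm: int = 1000, seed: int = 0,
                         min_size: int = 10, max_size: int = 500,
                         weight_p: float = 1.0) -> EnrichmentResult:
    """GSEA-style pre-ranked enrichment with a feature-label permutation null.

    For each permutation one relabeling of the ranked list is drawn and every
    eligible set is scored under it.  p is empirical and one-sided by ES sign
    (with +1 smoothing); NES divides ES by the mean |null ES| of the same
    sign; BH q is computed across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = ranked.sort_values(ascending=False, kind="mergesort")
    n = len(ranked)
    idx_of = {f: i for i, f in enumerate(ranked.index)}
    stats_arr = ranked.to_numpy(dtype=float)

    eligible: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    n_unmapped: dict[str, int] = {}
    for name, members in collection.sets.items():
        pos = np.array(sorted(idx_of[m] for m in members if m in idx_of))
        n_unmapped[name] = len(members) - pos.size
        if not min_size <= pos.size <= max_size:
            skipped[name] = f"mapped size {pos.size} outside [{min_size}, {max_size}]"
            continue
        eligible[name] = pos
    if not eligible:
        raise ValueError("no eligible gene set after size filtering")

    observed: dict[str, tuple[float, int]] = {
        name: _es_from_positions(pos, stats_arr, n, weight_p)
        for name, pos in eligible.items()}

    rng = np.random.default_rng(seed)
    null_es = {name: np.empty(n_perm) for name in eligible}
    inv = np.empty(n, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(n)
        inv[perm] = np.arange(n)
        for name, pos in eligible.items():
            null_es[name][b] = _es_from_positions(
                np.sort(inv[pos]), stats_arr, n, weight_p)[0]

    rows, leading = [], {}
    for name, pos in eligible.items():
        es, es_pos = observed[name]
        null = null_es[name]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            p, nes = 1.0 / (n_perm + 1), np.nan
        else:
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
            mean_abs = np.mean(np.abs(same))
            nes = es / mean_abs if mean_abs > 0 else np.nan
        members = [ranked.index[i] for i in pos]
        if es >= 0:
            leading[name] = [ranked.index[i] for i in pos if i <= es_pos]
        else:
            leading[name] = [ranked.index[i] for i in pos if i >= es_pos]
        rows.append({"set": name, "es": es, "nes": nes, "p": p,
                     "size_used": pos.size, "n_unmapped": n_unmapped[name],
                     "n_members": len(members)})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return EnrichmentResult(table, "preranked", leading, skipped)


# ---------------------------------------------------------------------------
# KS enrichment in per-pair concordance
# ---------------------------------------------------------------------------

def ks_concordance_enrichment(per_pair_rho: ConcordanceResult,
                              collection: GeneSetCollection,
                              min_mapped: int = 5) -> EnrichmentResult:
    """Two-sample two-sided KS of in-set vs out-of-set per-pair rho.

    D is signed positive when the in-set median exceeds the out-of-set
    median.  Sets with < ``min_mapped`` mapped pairs are skipped and
    recorded.  Output is sorted by q then |D| descending.
    """
    if per_pair_rho.mode != "across_subject":
        raise ValueError("expected an across_subject ConcordanceResult")
    scores = per_pair_rho.scores.dropna()
    gene_of = {key: key.split("|", 1)[1] for key in scores.index}
    gene_rho: dict[str, float] = {}
    for key, rho in scores.items():
        gene_rho.setdefault(gene_of[key], float(rho))
    all_genes = set(gene_rho)

    rows, skipped = [], {}
    for name, members in collection.sets.items():
        in_genes = [m for m in members if m in all_genes]
        if len(in_genes) < min_mapped:
            skipped[name] = f"only {len(in_genes)} mapped pairs"
            continue
        in_set = set(in_genes)
        in_vals = np.array([gene_rho[g] for g in in_genes])
        out_vals = np.array([v for g, v in gene_rho.items() if g not in in_set])
        if out_vals.size == 0:
            skipped[name] = "no background pairs"
            continue
        res = stats.ks_2samp(in_vals, out_vals, alternative="two-sided")
        sign = 1.0 if np.median(in_vals) >= np.median(out_vals) else -1.0
        rows.append({"set": name, "ks_d": sign * float(res.statistic),
                     "p": float(res.pvalue), "size_used": len(in_genes)})
    if not rows:
        raise ValueError("no gene set with enough mapped pairs")
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["q", "ks_d"], ascending=[True, False],
                              key=lambda s: s.abs() if s.name == "ks_d" else s)
    return EnrichmentResult(table, "ks_concordance", skipped=skipped)
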