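"""Consensus non-negative matrix factorization subtyping.

Factorization minimizes the generalized Kullback-Leibler divergence with
multiplicative updates from seeded random initializations.  Consensus
clustering repeats the factorization from distinct restarts per K, averages
the sample co-clustering (connectivity) matrices, and selects the K whose
consensus matrix has the highest cophenetic correlation; final labels come
from cutting the consensus dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_config import OmicsMatrix
from .survival_scores import FisherResult, fisher_exact, association_table


@dataclass
class NMFResult:
    k: int
    w: np.ndarray                 # features x K
    h: np.ndarray                 # K x samples
    objective_trace: list[float]
    seed: int

    def __post_init__(self) -> None:
        if (self.w < 0).any() or (self.h < 0).any():
            raise ValueError("W and H must be non-negative")
        tr = np.asarray(self.objective_trace)
        if (np.diff(tr) > 1e-8 * max(1.0, tr[0])).any():
            raise ValueError("KL objective increased during updates")

    @property
    def assignments(self) -> np.ndarray:
        """Hard sample assignment: argmax row of H (0-based)."""
        return np.argmax(self.h, axis=0)


@dataclass
class ConsensusResult:
    consensus: dict[int, np.ndarray]      # K -> samples x samples in [0, 1]
    cophenetic: dict[int, float]
    selected_k: int
    assignments: pd.Series                # sample -> 1..K
    sample_ids: list[str]

    def __post_init__(self) -> None:
        for k, c in self.consensus.items():
            if not np.allclose(c, c.T):
                raise ValueError("consensus matrix must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("consensus diagonal must be 1")
            if (c < -1e-9).any() or (c > 1 + 1e-9).any():
                raise ValueError("consensus entries must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def select_variable(matrix: OmicsMatrix, mad_cutoff: float = 0.5,
                    top_n: int = 1000) -> OmicsMatrix:
    """Keep features with MAD >= cutoff, then the top_n by MAD.

    MAD is the unscaled median absolute deviation from the feature median,
    computed across samples.  Ties in MAD break by feature id so the output
    is deterministic.
    """
    med = np.median(matrix.values, axis=1, keepdims=True)
    mad = np.median(np.abs(matrix.values - med), axis=1)
    passing = [(m, f) for m, f in zip(mad, matrix.feature_ids) if m >= mad_cutoff]
    if not passing:
        raise ValueError("no feature passes the MAD cutoff")
    passing.sort(key=lambda t: (-t[0], t[1]))
    kept = [f for _, f in passing[:top_n]]
    return matrix.select_features(kept)


# ---------------------------------------------------------------------------
# KL-NMF with multiplicative updates
# ---------------------------------------------------------------------------

def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    mask = v > 0
    eps = 1e-12
    return float(np.sum(v[mask] * np.log(v[mask] / (wh[mask] + eps)))
                 - v.sum() + wh.sum())


def nmf_factorize(v: np.ndarray, k: int, seed: int = 0,
                  max_iter: int = 200, tol: float = 1e-5) -> NMFResult:
    """Multiplicative-update KL-NMF from a seeded random initialization.

    Stops when the relative objective change drops below ``tol`` or after
    ``max_iter`` sweeps; the objective trace is recorded and checked to be
    non-increasing.
    """
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("input matrix must be non-negative")
    if (v.sum(axis=1) == 0).any() or (v.sum(axis=0) == 0).any():
        raise ValueError("remove all-zero rows/columns before factorizing")
    if not 1 <= k < min(v.shape):
        raise ValueError(f"K={k} must satisfy 1 <= K < min(dims)")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(v.mean() / k)
    w = rng.uniform(0.5, 1.5, size=(v.shape[0], k)) * scale
    h = rng.uniform(0.5, 1.5, size=(k, v.shape[1])) * scale
    eps = 1e-12
    trace = [_kl_divergence(v, w @ h)]
    for _ in range(max_iter):
        wh = w @ h + eps
        h *= (w.T @ (v / wh)) / np.maximum(w.sum(axis=0)[:, None], eps)
        wh = w @ h + eps
        w *= ((v / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(v, w @ h)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= tol * max(abs(prev), 1.0):
            break
    return NMFResult(k, w, h, trace, seed)


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------

def connectivity_matrix(assignments: np.ndarray) -> np.ndarray:
    a = np.asarray(assignments)
    return (a[:, None] == a[None, :]).astype(float)


def cophenetic_coefficient(consensus: np.ndarray) -> tuple[float, np.ndarray]:
    """Cophenetic correlation of 1 - consensus under average linkage.

    Returns (coefficient, linkage matrix).  A perfectly stable clustering
    (0/1 consensus) yields a coefficient of 1 by convention, because the
    cophenetic distances then reproduce 1 - consensus exactly.
    """
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    coph_dist = hierarchy.cophenet(link)
    if np.std(condensed) == 0 or np.std(coph_dist) == 0:
        # degenerate: all distances equal; exact reproduction counts as 1
        coef = 1.0 if np.allclose(condensed, coph_dist) else 0.0
    else:
        coef = float(np.corrcoef(condensed, coph_dist)[0, 1])
    return coef, link


def consensus_cluster(matrix: OmicsMatrix, k_min: int = 2, k_max: int = 7,
                      n_restarts: int = 30, seed: int = 0,
                      max_iter: int = 200, tol: float = 1e-5,
                      ) -> ConsensusResult:
    """Consensus NMF over K = k_min..k_max with restart-averaged connectivity.

    Restart seeds derive deterministically from ``seed``.  The selected K
    maximizes the cophenetic coefficient; final assignments cut the selected
    consensus dendrogram into K clusters (labels 1..K).
    """
    if n_restarts < 10:
        raise ValueError("n_restarts must be >= 10")
    v = matrix.values
    n = v.shape[1]
    if k_max >= n:
        raise ValueError("k_max must be < n_samples")
    seeds = np.random.SeedSequence(seed).generate_state(
        (k_max - k_min + 1) * n_restarts)
    consensus: dict[int, np.ndarray] = {}
    coph: dict[int, float] = {}
    links: dict[int, np.ndarray] = {}
    si = 0
    for k in range(k_min, k_max + 1):
        acc = np.zeros((n, n))
        for _ in range(n_restarts):
            res = nmf_factorize(v, k, seed=int(seeds[si]),
                                max_iter=max_iter, tol=tol)
            si += 1
            acc += connectivity_matrix(res.assignments)
        cons = acc / n_restarts
        np.fill_diagonal(cons, 1.0)
        consensus[k] = cons
        coph[k], links[k] = cophenetic_coefficient(cons)
    selected = max(coph, key=lambda k: (coph[k], -k))
    labels = hierarchy.fcluster(links[selected], t=selected,
                                criterion="maxclust")
    # relabel so group 1 is the largest cluster (stable reporting convention)
    sizes = pd.Series(labels).value_counts()
    remap = {old: i + 1 for i, old in enumerate(sizes.index)}
    labels = np.array([remap[l] for l in labels])
    assignments = pd.Series(labels, index=matrix.sample_ids)
    return ConsensusResult(consensus, coph, selected, assignments,
                           list(matrix.sample_ids))


def associate_groups(assignments: pd.Series,
                     flags: pd.Series | dict) -> FisherResult:
    """Fisher's exact test of a binary per-sample annotation vs two groups."""
    flags = pd.Series(flags)
    groups = sorted(assignments.unique())
    if len(groups) != 2:
        raise ValueError("association test requires exactly 2 groups")
    a = list(assignments.index[assignments == groups[0]])
    b = list(assignments.index[assignments == groups[1]])
    if not a or not b:
        raise ValueError("a group is empty")
    table = association_table(flags.to_dict(), a, b)
    return fisher_exact(table)
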