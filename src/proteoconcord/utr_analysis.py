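"""Fold-change contrast between a flagged gene set and the background.

Used for the 3'UTR-shortening question: do flagged genes show a larger
tumor/normal protein fold change than other genes, without a matching mRNA
change?  Per-gene folds are paired medians of tumor - normal differences on
the transformed (log2) scale; the set-vs-background contrast is an unpaired
rank-sum across genes (a signed-rank variant on trimmed matched samples is
also reported, since either reading of a "two-set rank test" is defensible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_config import OmicsMatrix, PairMap
from .concordance import rank_sum_test
from .preprocess import signed_rank_test


@dataclass
class FoldChangeContrast:
    set_name: str
    n_mapped: int
    n_background: int
    protein_fold_set: float
    protein_fold_background: float
    mrna_fold_set: float
    mrna_fold_background: float
    protein_p: float
    mrna_p: float
    protein_p_signed_rank: float
    mrna_p_signed_rank: float

    def __post_init__(self) -> None:
        for f in (self.protein_fold_set, self.protein_fold_background,
                  self.mrna_fold_set, self.mrna_fold_background):
            if not f > 0:
                raise ValueError("fold changes must be positive")


def _per_gene_paired_folds(matrix: OmicsMatrix, feature_ids: list[str],
                           pairs: list[tuple[str, str]]) -> np.ndarray:
    """Median over pairs of (tumor - normal) per feature, NaN-aware."""
    sub = matrix.select_features(feature_ids)
    ti = sub.sample_index([t for t, _ in pairs])
    ni = sub.sample_index([n for _, n in pairs])
    diffs = sub.values[:, ti] - sub.values[:, ni]
    with np.errstate(all="ignore"):
        return np.nanmedian(diffs, axis=1)


def foldchange_contrast(protein_transformed: OmicsMatrix,
                        mrna: OmicsMatrix,
                        pairs: list[tuple[str, str]],
                        gene_set: list[str],
                        pairmap: PairMap,
                        set_name: str = "flagged",
                        robust: bool = False) -> FoldChangeContrast:
    """Contrast per-gene paired log2 folds between a flagged set and the rest.

    ``pairs`` lists (tumor_sample, normal_sample) ids present in both
    matrices; ``gene_set`` holds flagged gene ids, mapped to proteins through
    ``pairmap``.  Fold changes are 2^(mean per-gene log2 fold) — or
    2^(median ...) with ``robust`` — and the contrast p-values come from a
    two-sided rank-sum across genes (plus a signed-rank variant on the
    size-trimmed set/background fold lists).
    """
    usable = [(t, n) for t, n in pairs
              if t in protein_transformed.sample_ids
              and n in protein_transformed.sample_ids
              and t in mrna.sample_ids and n in mrna.sample_ids]
    if len(usable) < 6:
        raise ValueError(f"need >= 6 complete tissue pairs, got {len(usable)}")

    gene_of = pairmap.as_dict()
    mrna_genes = set(mrna.feature_ids)
    mapped = [(p, gene_of[p]) for p in protein_transformed.feature_ids
              if p in gene_of and gene_of[p] in mrna_genes]
    flagged = set(gene_set)
    set_pairs = [(p, g) for p, g in mapped if g in flagged]
    bg_pairs = [(p, g) for p, g in mapped if g not in flagged]
    if len(set_pairs) < 10:
        raise ValueError(f"only {len(set_pairs)} flagged genes mapped (need >= 10)")

    prot_set = _per_gene_paired_folds(protein_transformed,
                                      [p for p, _ in set_pairs], usable)
    prot_bg = _per_gene_paired_folds(protein_transformed,
                                     [p for p, _ in bg_pairs], usable)
    rna_set = _per_gene_paired_folds(mrna, [g for _, g in set_pairs], usable)
    rna_bg = _per_gene_paired_folds(mrna, [g for _, g in bg_pairs], usable)

    summarize = np.nanmedian if robust else np.nanmean

    def fold(x: np.ndarray) -> float:
        return float(2.0 ** summarize(x))

    def contrast(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        _, p_rs = rank_sum_test(a, b)
        rng = np.random.default_rng(0)
        m = min(a.size, b.size)
        bi = np.sort(rng.choice(b.size, size=m, replace=False))
        _, p_sr = signed_rank_test(a[np.sort(rng.choice(a.size, size=m,
                                                        replace=False))]
                                   - b[bi])
        return p_rs, p_sr

    protein_p, protein_p_sr = contrast(prot_set, prot_bg)
    mrna_p, mrna_p_sr = contrast(rna_set, rna_bg)
    return FoldChangeContrast(
        set_name=set_name,
        n_mapped=len(set_pairs),
        n_background=len(bg_pairs),
        protein_fold_set=fold(prot_set),
        protein_fold_background=fold(prot_bg),
        mrna_fold_set=fold(rna_set),
        mrna_fold_background=fold(rna_bg),
        protein_p=protein_p,
        mrna_p=mrna_p,
        protein_p_signed_rank=protein_p_sr,
        mrna_p_signed_rank=mrna_p_sr,
    )
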