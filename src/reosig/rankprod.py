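"""Paired differential expression via the Rank Product statistic.

For each same-patient FF/FFPE pair, genes are ranked by their fold change
(FFPE + pseudocount) / (FF + pseudocount).  The Rank Product of a gene is
the geometric mean of its fold-change ranks across pairs — descending
ranks for up-regulation (rank 1 = largest fold change), ascending for
down-regulation.  Significance comes from permuting gene labels within
each pair: the pooled null RP distribution yields per-gene p-values and
the RP convention's percentage-of-false-positives FDR estimate
(expected false positives at the gene's RP over its rank in the observed
RP ordering), rather than Benjamini-Hochberg.

Being rank-based, RP is insensitive to transformations that preserve the
fold-change ordering of genes within each pair (e.g. per-sample scaling),
which is what makes it robust to batch effects between the FF and FFPE
assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata

from .io import PairedCohort
from .ranking import ReoError

__all__ = [
    "PairedFoldChanges",
    "paired_fold_changes",
    "rank_product_test",
    "fold_change_bins",
    "DirectionConsistency",
    "direction_consistency_test",
]

FOLD_CHANGE_BIN_LABELS = ("[0,1)", "[1,2)", "[2,3)", ">=3")


@dataclass
class PairedFoldChanges:
    """Per-pair FFPE/FF fold changes (genes x pairs) and the per-gene mean
    log2 fold change across pairs."""

    fold_changes: pd.DataFrame
    mean_log2fc: pd.Series
    pseudocount: float


def paired_fold_changes(
    cohort: PairedCohort, pseudocount: float = 1.0
) -> PairedFoldChanges:
    """Fold change (ffpe + pseudocount)/(ff + pseudocount) per gene per
    pair, plus the mean log2 fold change across pairs."""
    if pseudocount <= 0:
        raise ReoError(f"pseudocount must be > 0: {pseudocount}")
    if cohort.n_pairs == 0:
        raise ReoError("cohort has an empty pairing")
    cols = {}
    for ff_id, ffpe_id, ff_v, fp_v in cohort.iter_pairs():
        cols[f"{ff_id}|{ffpe_id}"] = (fp_v + pseudocount) / (ff_v + pseudocount)
    frame = pd.DataFrame(cols, index=cohort.ff.data.index)
    mean_l2 = np.log2(frame).mean(axis=1)
    mean_l2.name = "mean_log2fc"
    return PairedFoldChanges(frame, mean_l2, pseudocount)


def _rank_product(ranks: np.ndarray) -> np.ndarray:
    # geometric mean across pairs, in log space for numerical safety
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product_test(
    cohort: PairedCohort,
    n_perm: int = 100,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank Product test for paired FF/FFPE differential expression.

    Returns one row per gene: RP_up, RP_down, permutation p-values,
    permutation-FDR estimates and the mean log2 fold change.  The null
    distribution permutes each pair's observed rank vector (gene-label
    permutation within pairs), so tie structure is preserved;
    ``n_perm`` >= 100 is required for stable FDR estimates.
    """
    if n_perm < 100:
        raise ReoError(f"n_perm must be >= 100 for stable estimates: {n_perm}")
    if cohort.n_pairs < 2:
        raise ReoError("rank product needs at least 2 sample pairs")
    fc = paired_fold_changes(cohort, pseudocount)
    x = fc.fold_changes.to_numpy(dtype=float)
    n_genes, n_pairs = x.shape
    r_up = rankdata(-x, method="average", axis=0)   # 1 = most up-regulated
    r_down = rankdata(x, method="average", axis=0)  # 1 = most down-regulated
    rp_up = _rank_product(r_up)
    rp_down = _rank_product(r_down)

    rng = np.random.default_rng(seed)
    null_up = np.empty((n_perm, n_genes))
    null_down = np.empty((n_perm, n_genes))
    for p in range(n_perm):
        pu = np.empty_like(r_up)
        pdn = np.empty_like(r_down)
        for c in range(n_pairs):
            perm = rng.permutation(n_genes)
            pu[:, c] = r_up[perm, c]
            pdn[:, c] = r_down[perm, c]
        null_up[p] = _rank_product(pu)
        null_down[p] = _rank_product(pdn)

    def _p_and_fdr(rp: np.ndarray, null: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pool = np.sort(null.ravel())
        count = np.searchsorted(pool, rp, side="right")
        pvals = (count + 1) / (pool.size + 1)
        efp = count / n_perm  # expected false positives at each gene's RP
        order = np.argsort(rp, kind="stable")
        rank_pos = np.empty(n_genes)
        rank_pos[order] = np.arange(1, n_genes + 1)
        fdr = efp / rank_pos
        # enforce monotone non-decreasing FDR along the RP ordering
        sorted_fdr = fdr[order]
        sorted_fdr = np.minimum.accumulate(sorted_fdr[::-1])[::-1]
        out = np.empty(n_genes)
        out[order] = np.minimum(sorted_fdr, 1.0)
        return pvals, out

    p_up, fdr_up = _p_and_fdr(rp_up, null_up)
    p_down, fdr_down = _p_and_fdr(rp_down, null_down)
    direction = np.where(fc.mean_log2fc.to_numpy() >= 0, "up", "down")
    return pd.DataFrame(
        {
            "RP_up": rp_up,
            "RP_down": rp_down,
            "p_up": p_up,
            "p_down": p_down,
            "fdr_up": fdr_up,
            "fdr_down": fdr_down,
            "mean_log2fc": fc.mean_log2fc.to_numpy(),
            "direction": direction,
        },
        index=fc.fold_changes.index,
    )


def fold_change_bins(fc: PairedFoldChanges, deg_ids) -> pd.Series:
    """Histogram of differentially expressed genes by |mean log2 fold
    change|: bins [0,1), [1,2), [2,3), >=3.  The bins at or beyond 1 are
    the genes with at least 2-fold change."""
    deg_ids = list(deg_ids)
    unknown = [g for g in deg_ids if g not in fc.mean_log2fc.index]
    if unknown:
        raise ReoError(f"unknown DEG ids: {unknown[:5]}")
    mag = fc.mean_log2fc.loc[deg_ids].abs().to_numpy()
    edges = [0.0, 1.0, 2.0, 3.0, np.inf]
    counts = np.histogram(mag, bins=edges)[0]
    return pd.Series(counts, index=list(FOLD_CHANGE_BIN_LABELS), name="n_genes")


@dataclass(frozen=True)
class DirectionConsistency:
    n_overlap: int
    n_consistent: int
    consistent_fraction: float
    p_value: float


def direction_consistency_test(
    deg_directions: Mapping[str, Mapping[str, int] | pd.Series],
) -> DirectionConsistency:
    """Agreement of DEG deregulation directions across tissue types.

    ``deg_directions`` maps tissue name -> {gene -> direction sign}
    (+1 up in FFPE, -1 down).  Over the genes present in every tissue's
    map, counts those with the identical nonzero direction everywhere and
    tests that count against chance (two-sided exact binomial, p = 0.5).
    """
    if len(deg_directions) < 2:
        raise ReoError("need DEG direction maps for at least 2 tissues")
    maps = {t: pd.Series(d) for t, d in deg_directions.items()}
    shared: set[str] | None = None
    for s in maps.values():
        shared = set(s.index) if shared is None else shared & set(s.index)
    assert shared is not None
    if not shared:
        raise ReoError("no gene is shared by all DEG sets")
    genes = sorted(shared)
    signs = np.stack([np.sign(s.loc[genes].to_numpy(dtype=float)) for s in maps.values()])
    consistent = (signs != 0).all(axis=0) & (signs == signs[0]).all(axis=0)
    n, k = len(genes), int(consistent.sum())
    p = binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return DirectionConsistency(
        n_overlap=n, n_consistent=k,
        consistent_fraction=k / n, p_value=float(p),
    )
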