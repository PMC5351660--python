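"""Ranks, REO encoding and FF-vs-FFPE consistency scoring.

Within each sample, genes are ranked by expression in ascending order
(rank 1 = lowest; exact ties get midranks).  The relative expression
ordering (REO) of a gene pair (i, j) is the sign of ``expr_i - expr_j``.
The consistency score between a fresh-frozen (FF) sample and its paired
FFPE sample is k/n: of the n evaluable gene pairs, k keep the same
ordering in both samples.  Gene pairs with the smallest within-sample rank
difference ``Rij = |Ri - Rj|`` in the FF sample — the closest expression
levels — can optionally be excluded before scoring, since their orderings
are the ones most easily flipped by measurement noise and RNA degradation.

All pair-level work is blocked (see :mod:`reosig._pairs`) so that cohorts
with 20,000+ genes (~2x10^8 pairs) stream through bounded memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._pairs import DEFAULT_BLOCK, pair_blocks, upper_mask
from .io import ExpressionMatrix, PairedCohort

__all__ = [
    "ReoError",
    "NoEvaluablePairsError",
    "rank_sample",
    "rank_matrix",
    "count_gene_pairs",
    "rank_diff",
    "exclusion_mask",
    "consistency_score",
    "cohort_consistency",
    "ConsistencyRecord",
    "PairConsistencyReport",
]


class ReoError(ValueError):
    """Invalid input to a REO computation."""


class NoEvaluablePairsError(ReoError):
    """Every gene pair was excluded or tied; the score is undefined."""


def rank_sample(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Ascending ranks of one sample's expression vector (1 = lowest).

    Exact ties receive the midrank of the positions they span, so ranks
    are real-valued.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ReoError("cannot rank an empty expression vector")
    if not np.isfinite(v).all():
        raise ReoError("expression values must be finite")
    return rankdata(v, method="average")


def rank_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample ascending ranks for a whole matrix (genes x samples)."""
    ranks = rankdata(m.values, method="average", axis=0)
    return pd.DataFrame(ranks, index=m.data.index, columns=m.data.columns)


def count_gene_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, C(n, 2)."""
    if n_genes < 2:
        raise ReoError("need at least 2 genes to form pairs")
    return n_genes * (n_genes - 1) // 2


def rank_diff(ranks: np.ndarray, i: int, j: int) -> float:
    """Absolute within-sample rank difference Rij = |Ri - Rj|."""
    if i == j:
        raise ReoError("rank_diff requires two distinct genes")
    r = np.asarray(ranks, dtype=float)
    return float(abs(r[i] - r[j]))


# ---------------------------------------------------------------------------
# Exclusion of closest-expression pairs
# ---------------------------------------------------------------------------

def _n_excluded(fraction: float, n_pairs: int) -> int:
    if not 0.0 <= fraction < 1.0:
        raise ReoError(f"exclusion fraction must be in [0, 1): {fraction}")
    # guard against float artifacts like 0.2*10 = 2.0000000000000004
    return int(math.floor(fraction * n_pairs + 1e-9))


@dataclass(frozen=True)
class _Cutoff:
    """Exclusion rule: drop pairs with doubled rank diff < value, plus the
    listed boundary pair codes (i*n+j) at exactly the cutoff value (or all
    pairs at the cutoff when all_at_cut is set)."""

    value: int
    all_at_cut: bool
    boundary: np.ndarray  # sorted codes i*n+j, empty if all_at_cut


def _exclusion_cutoff(
    ranks: np.ndarray,
    gene_ids: Sequence[str],
    n_excl: int,
    block: int = DEFAULT_BLOCK,
) -> _Cutoff | None:
    """Determine which pairs the smallest-Rij exclusion removes.

    Rank diffs are doubled to integers (midranks are half-integers) so an
    exact histogram over at most 2n distinct values suffices; ties at the
    cutoff are broken by lexicographic (gene_id_i, gene_id_j) order.
    """
    if n_excl == 0:
        return None
    n = len(ranks)
    d2 = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(np.int64)
    hist = np.zeros(2 * n, dtype=np.int64)
    for i0, i1, j0, j1 in pair_blocks(n, block):
        dd = np.abs(d2[i0:i1, None] - d2[None, j0:j1])
        mask = upper_mask(i0, i1, j0, j1)
        hist += np.bincount(dd[mask], minlength=2 * n)
    cum = np.cumsum(hist)
    cut = int(np.searchsorted(cum, n_excl, side="left"))
    below = int(cum[cut] - hist[cut])
    m = n_excl - below
    if m == hist[cut]:
        return _Cutoff(cut, True, np.empty(0, dtype=np.int64))
    # partial exclusion at the cutoff: rank boundary pairs lexicographically
    keys: list[tuple[str, str, int]] = []
    ids = [str(g) for g in gene_ids]
    for i0, i1, j0, j1 in pair_blocks(n, block):
        dd = np.abs(d2[i0:i1, None] - d2[None, j0:j1])
        at = (dd == cut) & upper_mask(i0, i1, j0, j1)
        if at.any():
            ii, jj = np.nonzero(at)
            for bi, bj in zip(ii + i0, jj + j0):
                a, b = ids[bi], ids[bj]
                if a > b:
                    a, b = b, a
                keys.append((a, b, int(bi) * n + int(bj)))
    keys.sort()
    boundary = np.sort(np.array([c for _, _, c in keys[:m]], dtype=np.int64))
    return _Cutoff(cut, False, boundary)


def exclusion_mask(
    ff_ranks: np.ndarray,
    gene_ids: Sequence[str],
    fraction: float,
    block: int = DEFAULT_BLOCK,
) -> set[tuple[str, str]]:
    """The set of gene pairs excluded as closest-expression pairs.

    Exactly ``floor(fraction * n_pairs)`` pairs are removed — those with
    the smallest Rij in the FF sample, ties at the cut broken by
    lexicographic gene-ID pair.  Pairs are returned as (gene_a, gene_b)
    tuples with gene_a < gene_b lexicographically.

    This materializes the set and is meant for moderate gene counts; the
    scoring kernels apply the same rule in streaming form.
    """
    r = np.asarray(ff_ranks, dtype=float)
    n = r.size
    ids = [str(g) for g in gene_ids]
    if len(ids) != n:
        raise ReoError("gene_ids length must match the rank vector")
    n_excl = _n_excluded(fraction, count_gene_pairs(n) if n >= 2 else 0)
    cutoff = _exclusion_cutoff(r, ids, n_excl, block)
    if cutoff is None:
        return set()
    out: set[tuple[str, str]] = set()
    d2 = np.rint(2.0 * r).astype(np.int64)
    bset = set(cutoff.boundary.tolist())
    for i in range(n):
        for j in range(i + 1, n):
            d = abs(int(d2[i]) - int(d2[j]))
            if d < cutoff.value or (
                d == cutoff.value and (cutoff.all_at_cut or i * n + j in bset)
            ):
                a, b = ids[i], ids[j]
                out.add((a, b) if a < b else (b, a))
    return out


# ---------------------------------------------------------------------------
# Consistency scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyRecord:
    """Per paired-sample consistency of REOs at one exclusion fraction."""

    ff_id: str
    ffpe_id: str
    fraction: float
    n_evaluated: int
    k_consistent: int
    n_tied: int
    n_excluded: int

    @property
    def score(self) -> float:
        return self.k_consistent / self.n_evaluated


def consistency_score(
    ff_sample: np.ndarray,
    ffpe_sample: np.ndarray,
    fraction: float = 0.0,
    gene_ids: Sequence[str] | None = None,
    block: int = DEFAULT_BLOCK,
    ff_id: str = "FF",
    ffpe_id: str = "FFPE",
) -> ConsistencyRecord:
    """Consistency score k/n of gene-pair orderings between two matched
    samples over an identical gene list.

    Pairs with the smallest FF rank difference are excluded first
    (``fraction`` of all pairs); among the remainder a pair is consistent
    iff ``sign(expr_i - expr_j)`` is identical and nonzero in both
    samples.  Pairs tied in either sample are excluded from both k and n
    and reported as ``n_tied``.
    """
    ff = np.asarray(ff_sample, dtype=float)
    fp = np.asarray(ffpe_sample, dtype=float)
    if ff.shape != fp.shape:
        raise ReoError("FF and FFPE vectors must cover the identical gene list")
    n = ff.size
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n)]
    total = count_gene_pairs(n)
    n_excl = _n_excluded(fraction, total)
    r = rank_sample(ff)
    cutoff = _exclusion_cutoff(r, gene_ids, n_excl, block)
    d2 = np.rint(2.0 * r).astype(np.int64)

    k = n_eval = ties = 0
    for i0, i1, j0, j1 in pair_blocks(n, block):
        valid = upper_mask(i0, i1, j0, j1)
        if cutoff is not None:
            dd = np.abs(d2[i0:i1, None] - d2[None, j0:j1])
            excl = dd < cutoff.value
            if cutoff.all_at_cut:
                excl |= dd == cutoff.value
            elif cutoff.boundary.size:
                at = (dd == cutoff.value) & valid
                if at.any():
                    ii, jj = np.nonzero(at)
                    codes = (ii + i0).astype(np.int64) * n + (jj + j0)
                    hit = np.searchsorted(cutoff.boundary, codes)
                    hit_ok = (hit < cutoff.boundary.size) & (
                        cutoff.boundary[np.minimum(hit, cutoff.boundary.size - 1)]
                        == codes
                    )
                    excl[ii[hit_ok], jj[hit_ok]] = True
            valid &= ~excl
        dff = ff[i0:i1, None] - ff[None, j0:j1]
        dfp = fp[i0:i1, None] - fp[None, j0:j1]
        tie = ((dff == 0) | (dfp == 0)) & valid
        ties += int(tie.sum())
        ev = valid & ~tie
        n_eval += int(ev.sum())
        k += int((ev & ((dff > 0) == (dfp > 0))).sum())

    if n_eval == 0:
        raise NoEvaluablePairsError(
            "no evaluable gene pairs remain after exclusions and ties"
        )
    return ConsistencyRecord(
        ff_id=ff_id, ffpe_id=ffpe_id, fraction=float(fraction),
        n_evaluated=n_eval, k_consistent=k, n_tied=ties, n_excluded=n_excl,
    )


@dataclass
class PairConsistencyReport:
    """Per-pair consistency records over one or more exclusion fractions,
    with the cohort mean score per fraction."""

    records: list[ConsistencyRecord]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ff_id": r.ff_id, "ffpe_id": r.ffpe_id, "fraction": r.fraction,
                "n": r.n_evaluated, "k": r.k_consistent, "ties": r.n_tied,
                "score": r.score,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def mean_scores(self) -> dict[float, float]:
        """Arithmetic mean of per-pair scores, keyed by exclusion fraction."""
        out: dict[float, list[float]] = {}
        for r in self.records:
            out.setdefault(r.fraction, []).append(r.score)
        return {f: float(np.mean(s)) for f, s in sorted(out.items())}

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        summary = pd.DataFrame(
            [
                {"ff_id": "__mean__", "ffpe_id": "", "fraction": f,
                 "n": "", "k": "", "ties": "", "score": s}
                for f, s in self.mean_scores().items()
            ]
        )
        pd.concat([frame, summary], ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.10g",
            lineterminator="\n",
        )


def cohort_consistency(
    cohort: PairedCohort,
    fractions: Sequence[float] = (0.0, 0.1, 0.2),
    block: int = DEFAULT_BLOCK,
) -> PairConsistencyReport:
    """Consistency scores for every paired sample at each exclusion
    fraction, plus cohort means."""
    if cohort.n_pairs == 0:
        raise ReoError("cohort has an empty pairing")
    genes = cohort.gene_ids
    records: list[ConsistencyRecord] = []
    for ff_id, ffpe_id, ff_v, fp_v in cohort.iter_pairs():
        for f in fractions:
            records.append(
                consistency_score(
                    ff_v, fp_v, fraction=f, gene_ids=genes, block=block,
                    ff_id=ff_id, ffpe_id=ffpe_id,
                )
            )
    return PairConsistencyReport(records)
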