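"""Mining highly stable REOs in accumulated cohorts.

A gene pair has a highly stable REO when one ordering direction
(expr_i > expr_j or expr_i < expr_j) holds in at least a high threshold
fraction — 99% by default — of an accumulated cohort, typically normal
tissue profiles pooled from several data sources.  Such pairs serve as a
gold standard against which individual samples (e.g. archival FFPE
blocks) are checked: the maintained fraction of stable REOs quantifies
how much ordering information survives RNA degradation.

Ties count toward neither direction, and support fractions always use the
full cohort size as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._pairs import DEFAULT_BLOCK, pair_blocks, upper_mask
from .io import ExpressionMatrix, MatrixValidationError
from .ranking import ReoError

__all__ = [
    "StablePairSet",
    "mine_stable_pairs",
    "maintained_fraction",
    "concat_cohorts",
]


@dataclass
class StablePairSet:
    """Gene pairs with a fixed ordering direction in >= threshold of a
    cohort.

    ``pairs`` columns: gene_i, gene_j (gene_i < gene_j lexicographically),
    direction ('gt' means expr_i > expr_j), support_fraction.
    """

    pairs: pd.DataFrame
    threshold: float
    cohort_size: int

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        out = self.pairs.copy()
        out["cohort_size"] = self.cohort_size
        out.to_csv(path, sep="\t", index=False, float_format="%.10g",
                   lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str | Path, threshold: float) -> "StablePairSet":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
        size = int(frame["cohort_size"].iloc[0]) if len(frame) else 0
        return cls(frame.drop(columns=["cohort_size"], errors="ignore"),
                   threshold=threshold, cohort_size=size)


def mine_stable_pairs(
    cohort: ExpressionMatrix,
    threshold: float = 0.99,
    block: int = DEFAULT_BLOCK,
) -> StablePairSet:
    """Find every gene pair whose majority ordering holds in at least
    ``threshold`` of the cohort's samples.

    Emits one row per qualifying unordered pair, in lexicographic gene-ID
    order, with the majority direction and its support fraction.
    """
    if not 0.5 < threshold <= 1.0:
        raise ReoError(
            f"stability threshold must be in (0.5, 1]: {threshold}"
        )
    if cohort.n_samples < 2:
        raise ReoError("stable-pair mining needs at least 2 samples")
    x = cohort.values
    ids = np.asarray(cohort.gene_ids, dtype=object)
    n, s = x.shape
    chunks: list[pd.DataFrame] = []
    for i0, i1, j0, j1 in pair_blocks(n, block):
        a = x[i0:i1, None, :]
        b = x[None, j0:j1, :]
        gt = (a > b).sum(axis=2)
        lt = (a < b).sum(axis=2)
        mask = upper_mask(i0, i1, j0, j1)
        frac_gt = gt / s
        frac_lt = lt / s
        sel = mask & ((frac_gt >= threshold) | (frac_lt >= threshold))
        if not sel.any():
            continue
        ii, jj = np.nonzero(sel)
        is_gt = frac_gt[ii, jj] >= threshold
        support = np.where(is_gt, frac_gt[ii, jj], frac_lt[ii, jj])
        gi = ids[ii + i0]
        gj = ids[jj + j0]
        # canonicalize to lexicographic pair order
        swap = gi > gj
        gi[swap], gj[swap] = gj[swap], gi[swap]
        is_gt = is_gt ^ swap
        chunks.append(pd.DataFrame({
            "gene_i": gi, "gene_j": gj,
            "direction": np.where(is_gt, "gt", "lt"),
            "support_fraction": support,
        }))
    if chunks:
        frame = pd.concat(chunks, ignore_index=True)
        frame = frame.sort_values(["gene_i", "gene_j"], kind="stable",
                                  ignore_index=True)
    else:
        frame = pd.DataFrame(
            columns=["gene_i", "gene_j", "direction", "support_fraction"]
        )
    return StablePairSet(frame, threshold=threshold, cohort_size=s)


def maintained_fraction(
    stable: StablePairSet,
    sample: pd.Series,
) -> tuple[float, int, int]:
    """Fraction of a stable pair set whose direction holds strictly in one
    sample.

    ``sample`` is an expression vector indexed by gene ID.  Pairs with a
    gene missing from the sample are dropped (and counted); ties in the
    sample count as not maintained.  Returns (fraction, n_evaluated,
    n_dropped).
    """
    if len(stable) == 0:
        raise ReoError("stable pair set is empty")
    index = sample.index
    pos_i = index.get_indexer(stable.pairs["gene_i"])
    pos_j = index.get_indexer(stable.pairs["gene_j"])
    have = (pos_i >= 0) & (pos_j >= 0)
    n_dropped = int((~have).sum())
    if not have.any():
        raise ReoError("no stable pair is evaluable in this sample")
    values = sample.to_numpy(dtype=float)
    vi = values[pos_i[have]]
    vj = values[pos_j[have]]
    want_gt = stable.pairs["direction"].to_numpy()[have] == "gt"
    held = np.where(want_gt, vi > vj, vi < vj)
    return float(held.mean()), int(held.size), n_dropped


def concat_cohorts(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate cohorts from different sources after
    intersecting their gene lists (order: first matrix's order)."""
    if not matrices:
        raise MatrixValidationError("no cohorts to concatenate")
    genes = [g for g in matrices[0].gene_ids]
    for m in matrices[1:]:
        keep = set(m.gene_ids)
        genes = [g for g in genes if g in keep]
    if not genes:
        raise MatrixValidationError("gene-list intersection is empty")
    frames = [m.data.loc[genes] for m in matrices]
    return ExpressionMatrix(pd.concat(frames, axis=1))
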