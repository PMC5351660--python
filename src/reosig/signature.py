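"""Reversal-gene-pair signature selection.

A reversal pair is a gene pair whose dominant within-sample ordering in
one phenotype class (e.g. cirrhotic liver: Ga > Gb in more than 85% of
samples) is the opposite of its dominant ordering in the other class
(HCC: Ga < Gb in more than 85% of samples).  Candidate reversal pairs are
ranked by the reversal-degree statistic

    avgRij = mean[Rij(class0)] * mean[Rij(class1)],

the product of the class-wise mean absolute rank differences of the pair
(Rij = |Ri - Rj| on whole-sample ascending ranks).  Ranking by this
product is equivalent to ranking by its geometric mean.  The top-k pairs
(k odd, so the downstream majority vote cannot deadlock) form the
signature.

The module-level functions implement each step; the statsmodels-style
:class:`ReversalPairSignatureModel` / :class:`SignatureResults` pair wraps
them for the common train-then-classify workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._pairs import DEFAULT_BLOCK, direction_counts, pair_blocks, upper_mask
from .io import ExpressionMatrix, MatrixValidationError
from .ranking import ReoError, rank_matrix

__all__ = [
    "SignaturePair",
    "Signature",
    "find_reversal_pairs",
    "score_pair",
    "score_pairs",
    "select_signature",
    "ReversalPairSignatureModel",
    "SignatureResults",
]


@dataclass(frozen=True)
class SignaturePair:
    """One ordered gene pair: gene_a > gene_b defines class 0."""

    gene_a: str
    gene_b: str
    consistency_class0: float
    consistency_class1: float
    score: float = float("nan")

    @property
    def class0_direction(self) -> str:
        return f"{self.gene_a}>{self.gene_b}"


@dataclass(frozen=True)
class Signature:
    """An ordered list of scored reversal pairs plus training metadata."""

    pairs: tuple[SignaturePair, ...]
    threshold: float
    class0_name: str = "class0"
    class1_name: str = "class1"

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            for g in (p.gene_a, p.gene_b):
                if g not in out:
                    out.append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "class0_direction": p.class0_direction,
                    "consistency_class0": p.consistency_class0,
                    "consistency_class1": p.consistency_class1,
                    "score": p.score,
                }
                for p in self.pairs
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g", lineterminator="\n")

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        threshold: float = 0.85,
        class0_name: str = "class0",
        class1_name: str = "class1",
    ) -> "Signature":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        pairs = tuple(
            SignaturePair(
                gene_a=row.gene_a,
                gene_b=row.gene_b,
                consistency_class0=float(row.consistency_class0),
                consistency_class1=float(row.consistency_class1),
                score=float(row.score),
            )
            for row in frame.itertuples()
        )
        return cls(pairs, threshold=threshold,
                   class0_name=class0_name, class1_name=class1_name)


def _shared_genes(class0: ExpressionMatrix, class1: ExpressionMatrix) -> list[str]:
    if class0.gene_ids == class1.gene_ids:
        return class0.gene_ids
    keep = set(class1.gene_ids)
    genes = [g for g in class0.gene_ids if g in keep]
    if not genes:
        raise MatrixValidationError("the two classes share no genes")
    return genes


def find_reversal_pairs(
    class0: ExpressionMatrix,
    class1: ExpressionMatrix,
    threshold: float = 0.85,
    block: int = DEFAULT_BLOCK,
) -> list[SignaturePair]:
    """All pairs whose dominant ordering in class 0 holds strictly in more
    than ``threshold`` of class-0 samples AND is reversed in more than
    ``threshold`` of class-1 samples.

    Ties count toward neither direction; comparisons are strict (>).
    Pairs are returned unscored, oriented so that gene_a > gene_b is the
    class-0 direction, sorted by (gene_a, gene_b).
    """
    if not 0.5 < threshold < 1.0:
        raise ReoError(f"reversal threshold must be in (0.5, 1): {threshold}")
    genes = _shared_genes(class0, class1)
    x0 = class0.subset_genes(genes).values
    x1 = class1.subset_genes(genes).values
    s0, s1 = x0.shape[1], x1.shape[1]
    n = len(genes)
    out: list[SignaturePair] = []
    for i0, i1, j0, j1 in pair_blocks(n, block):
        gt0, lt0 = direction_counts(x0, i0, i1, j0, j1)
        gt1, lt1 = direction_counts(x1, i0, i1, j0, j1)
        f0_gt, f0_lt = gt0 / s0, lt0 / s0
        f1_gt, f1_lt = gt1 / s1, lt1 / s1
        mask = upper_mask(i0, i1, j0, j1)
        fwd = mask & (f0_gt > threshold) & (f1_lt > threshold)
        rev = mask & (f0_lt > threshold) & (f1_gt > threshold)
        for sel, flip in ((fwd, False), (rev, True)):
            if not sel.any():
                continue
            ii, jj = np.nonzero(sel)
            for bi, bj in zip(ii, jj):
                gi, gj = genes[bi + i0], genes[bj + j0]
                if flip:
                    out.append(SignaturePair(
                        gene_a=gj, gene_b=gi,
                        consistency_class0=float(f0_lt[bi, bj]),
                        consistency_class1=float(f1_gt[bi, bj]),
                    ))
                else:
                    out.append(SignaturePair(
                        gene_a=gi, gene_b=gj,
                        consistency_class0=float(f0_gt[bi, bj]),
                        consistency_class1=float(f1_lt[bi, bj]),
                    ))
    out.sort(key=lambda p: (p.gene_a, p.gene_b))
    return out


def score_pair(
    pair: SignaturePair,
    class0_ranks: pd.DataFrame,
    class1_ranks: pd.DataFrame,
) -> float:
    """avgRij of one pair: the class-0 mean absolute rank difference times
    the class-1 mean absolute rank difference.  Ranks are whole-sample
    ascending ranks (genes x samples frames from :func:`rank_matrix`)."""
    d0 = (class0_ranks.loc[pair.gene_a] - class0_ranks.loc[pair.gene_b]).abs().mean()
    d1 = (class1_ranks.loc[pair.gene_a] - class1_ranks.loc[pair.gene_b]).abs().mean()
    return float(d0 * d1)


def score_pairs(
    pairs: Sequence[SignaturePair],
    class0: ExpressionMatrix,
    class1: ExpressionMatrix,
) -> list[SignaturePair]:
    """Score candidate pairs by avgRij, recomputing whole-sample ranks over
    the full shared gene list once per class."""
    genes = _shared_genes(class0, class1)
    r0 = rank_matrix(class0.subset_genes(genes))
    r1 = rank_matrix(class1.subset_genes(genes))
    return [replace(p, score=score_pair(p, r0, r1)) for p in pairs]


def select_signature(
    candidates: Sequence[SignaturePair],
    k: int = 5,
    threshold: float = 0.85,
    class0_name: str = "class0",
    class1_name: str = "class1",
) -> Signature:
    """Top-k candidates by descending avgRij (ties broken by lexicographic
    (gene_a, gene_b)); k must be odd for the majority rule."""
    if k % 2 == 0:
        raise ReoError(f"signature size k must be odd for majority voting: {k}")
    if k > len(candidates):
        raise ReoError(
            f"k={k} exceeds the {len(candidates)} available candidate pairs"
        )
    for p in candidates:
        if not np.isfinite(p.score):
            raise ReoError(f"candidate pair {p.gene_a},{p.gene_b} is unscored")
    ranked = sorted(candidates, key=lambda p: (-p.score, p.gene_a, p.gene_b))
    return Signature(tuple(ranked[:k]), threshold=threshold,
                     class0_name=class0_name, class1_name=class1_name)


# ---------------------------------------------------------------------------
# Model / results facade
# ---------------------------------------------------------------------------

class ReversalPairSignatureModel:
    """Trains a reversal-pair signature on two phenotype classes.

    Parameters
    ----------
    class0, class1
        Training expression matrices (genes x samples, linear scale) for
        the two phenotypes; gene lists are intersected if they differ.
    threshold
        Strict (>) per-class REO consistency required of a candidate
        reversal pair.  Default 0.85.
    class0_name, class1_name
        Labels used in classification output.
    """

    def __init__(
        self,
        class0: ExpressionMatrix,
        class1: ExpressionMatrix,
        threshold: float = 0.85,
        class0_name: str = "class0",
        class1_name: str = "class1",
        block: int = DEFAULT_BLOCK,
    ):
        self.class0 = class0
        self.class1 = class1
        self.threshold = threshold
        self.class0_name = class0_name
        self.class1_name = class1_name
        self.block = block

    def fit(self, k: int = 5) -> "SignatureResults":
        """Enumerate reversal pairs, score by avgRij, keep the top k."""
        candidates = find_reversal_pairs(
            self.class0, self.class1, self.threshold, block=self.block
        )
        if not candidates:
            raise ReoError(
                "no reversal pair passes the consistency threshold in both classes"
            )
        scored = score_pairs(candidates, self.class0, self.class1)
        sig = select_signature(
            scored, k=k, threshold=self.threshold,
            class0_name=self.class0_name, class1_name=self.class1_name,
        )
        return SignatureResults(self, sig, scored)


class SignatureResults:
    """Fitted signature plus the scored candidate pool and diagnostics."""

    def __init__(
        self,
        model: ReversalPairSignatureModel,
        signature: Signature,
        candidates: list[SignaturePair],
    ):
        self.model = model
        self.signature = signature
        self.candidates = candidates

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def classify(self, m: ExpressionMatrix) -> pd.DataFrame:
        from .classify import classify_matrix

        return classify_matrix(self.signature, m)

    def sensitivity(self, m: ExpressionMatrix, true_label: str) -> float:
        from .classify import evaluate

        return evaluate(self.signature, m, true_label)[0]

    def training_sensitivities(self) -> dict[str, float]:
        return {
            self.signature.class0_name: self.sensitivity(
                self.model.class0, self.signature.class0_name
            ),
            self.signature.class1_name: self.sensitivity(
                self.model.class1, self.signature.class1_name
            ),
        }

    def summary(self) -> str:
        sig = self.signature
        train = self.training_sensitivities()
        lines = [
            "Reversal-pair signature",
            "=" * 64,
            f"classes:            {sig.class0_name} (class0) vs {sig.class1_name} (class1)",
            f"consistency cutoff: > {sig.threshold:.2f} per class",
            f"candidate pairs:    {self.n_candidates}",
            f"signature size k:   {sig.k}",
            "-" * 64,
            f"{'gene_a':<12}{'gene_b':<12}{'cons0':>8}{'cons1':>8}{'avgRij':>14}",
        ]
        for p in sig.pairs:
            lines.append(
                f"{p.gene_a:<12}{p.gene_b:<12}"
                f"{p.consistency_class0:>8.3f}{p.consistency_class1:>8.3f}"
                f"{p.score:>14.2f}"
            )
        lines.append("-" * 64)
        for name, sens in train.items():
            lines.append(f"training sensitivity [{name}]: {sens:.4f}")
        return "\n".join(lines)
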