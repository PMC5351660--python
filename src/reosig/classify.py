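"""Majority-rule classification against a reversal-pair signature.

Each signature pair casts one vote per sample: class 0 if the pair's
class-0 ordering (gene_a > gene_b) holds strictly, class 1 if the reverse
holds strictly, a tie otherwise.  A sample is labelled class 0 only when
class-0 votes exceed half the signature size; everything else — including
tied votes — falls to class 1, the "otherwise" branch of the rule.
Because the vote depends only on within-sample orderings, the label is
invariant under any strictly increasing transform of the sample's
expression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .ranking import ReoError
from .signature import Signature

__all__ = [
    "MissingGeneError",
    "ClassificationResult",
    "classify_sample",
    "classify_matrix",
    "evaluate",
]


class MissingGeneError(ReoError):
    """A signature gene is absent from the sample's gene list."""


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    votes_class0: int
    votes_class1: int
    ties: int
    label: str


def _pair_values(sig: Signature, m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    index = m.data.index
    for g in sig.genes:
        if g not in index:
            raise MissingGeneError(f"signature gene {g!r} missing from input")
    a = m.data.loc[[p.gene_a for p in sig.pairs]].to_numpy(dtype=float)
    b = m.data.loc[[p.gene_b for p in sig.pairs]].to_numpy(dtype=float)
    return a, b


def classify_matrix(sig: Signature, m: ExpressionMatrix) -> pd.DataFrame:
    """Classify every sample of a matrix; one row per sample with vote
    counts and the majority-rule label."""
    if m.n_samples == 0:
        raise ReoError("matrix has no samples to classify")
    a, b = _pair_values(sig, m)  # k x n_samples each
    votes0 = (a > b).sum(axis=0)
    votes1 = (a < b).sum(axis=0)
    ties = sig.k - votes0 - votes1
    label = np.where(votes0 > sig.k / 2, sig.class0_name, sig.class1_name)
    return pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "votes_class0": votes0.astype(int),
            "votes_class1": votes1.astype(int),
            "ties": ties.astype(int),
            "label": label,
        }
    )


def classify_sample(sig: Signature, sample: pd.Series,
                    sample_id: str | None = None) -> ClassificationResult:
    """Classify one sample (expression vector indexed by gene ID)."""
    sid = sample_id if sample_id is not None else str(sample.name or "sample")
    m = ExpressionMatrix(sample.to_frame(name=sid))
    row = classify_matrix(sig, m).iloc[0]
    return ClassificationResult(
        sample_id=sid,
        votes_class0=int(row.votes_class0),
        votes_class1=int(row.votes_class1),
        ties=int(row.ties),
        label=str(row.label),
    )


def evaluate(
    sig: Signature, m: ExpressionMatrix, true_label: str
) -> tuple[float, pd.DataFrame]:
    """Per-dataset, per-class sensitivity: the fraction of samples (all
    sharing ``true_label``) assigned that label, plus per-sample votes."""
    if true_label not in (sig.class0_name, sig.class1_name):
        raise ReoError(
            f"true_label {true_label!r} is neither "
            f"{sig.class0_name!r} nor {sig.class1_name!r}"
        )
    frame = classify_matrix(sig, m)
    sensitivity = float((frame["label"] == true_label).mean())
    return sensitivity, frame
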