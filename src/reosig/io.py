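"""Expression-matrix I/O and preprocessing.

The universal input of every REO computation is a genes-by-samples matrix
of nonnegative, linear-scale expression values.  This module provides a
validated container (:class:`ExpressionMatrix`), plain-TSV readers/writers
(the lowest common denominator for GEO series-matrix exports and TCGA
level-3 tables), probe-to-gene aggregation and the all-zero gene filter
applied jointly over a paired fresh-frozen (FF) / FFPE cohort.

Missing values are not supported: every cell must parse as a finite,
nonnegative number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionError",
    "MatrixParseError",
    "MatrixValidationError",
    "ExpressionMatrix",
    "ProbeMap",
    "PairedCohort",
    "read_matrix",
    "write_matrix",
    "read_pairing",
    "write_pairing",
    "collapse_probes",
    "drop_allzero_genes",
    "drop_allzero_genes_matrix",
]


class ExpressionError(ValueError):
    """Base class for expression-data errors."""


class MatrixParseError(ExpressionError):
    """A file could not be parsed into a numeric matrix."""


class MatrixValidationError(ExpressionError):
    """A matrix violates an invariant (duplicates, negatives, NaNs...)."""


class ExpressionMatrix:
    """Genes x samples matrix of nonnegative linear-scale expression.

    Thin, validated wrapper around a :class:`pandas.DataFrame` whose index
    holds unique gene identifiers and whose columns hold unique sample
    identifiers.  Row and column order are semantically meaningful and
    preserved by every operation.
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True):
        if validate:
            self._validate(data)
        self._data = data

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        if not isinstance(data, pd.DataFrame):
            raise MatrixValidationError("expression data must be a DataFrame")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate gene IDs: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate sample IDs: {dups[:5]}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise MatrixValidationError("expression values must be numeric")
        if values.size:
            if not np.isfinite(values).all():
                raise MatrixValidationError("expression values must be finite")
            if (values < 0).any():
                raise MatrixValidationError("expression values must be >= 0")

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy(dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self._data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self._data.columns]

    @property
    def n_genes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's expression vector, indexed by gene."""
        return self._data[sample_id]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "ExpressionMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index([str(g) for g in gene_ids], name="gene_id"),
            columns=[str(s) for s in sample_ids],
        )
        return cls(frame)

    # -- manipulation ------------------------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self._data.index]
        if missing:
            raise MatrixValidationError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data.loc[list(genes)], validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self._data.equals(other._data)


def read_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-by-samples TSV: header row of sample IDs, gene IDs in
    column 1, numeric body.

    Raises :class:`MatrixParseError` naming the offending row and column
    for any cell that does not parse as a number, and
    :class:`MatrixValidationError` for duplicated gene or sample IDs.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise MatrixParseError(f"{path}: empty file")
    sample_ids = header.rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise MatrixValidationError(f"{path}: duplicate sample ID {sid!r}")
        seen.add(sid)

    try:
        raw = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str,
            keep_default_na=False, na_filter=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise MatrixParseError(f"{path}: empty file") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise MatrixValidationError(f"{path}: duplicate gene ID {dup!r}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        gene = raw.index[rows[0]]
        sample = raw.columns[cols[0]]
        cell = raw.iat[rows[0], cols[0]]
        raise MatrixParseError(
            f"{path}: malformed numeric cell {cell!r} at gene {gene!r}, "
            f"sample {sample!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "gene_id"
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric.astype(float))


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; ``read_matrix(write_matrix(m))`` round-trips."""
    frame = m.data.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Probe-to-gene aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeMap:
    """Explicit probe -> gene(s) mapping.

    A probe may map to zero, one or many genes; only probes mapping to
    exactly one gene contribute expression values after collapsing.
    """

    mapping: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ProbeMap":
        acc: dict[str, list[str]] = {}
        for probe, gene in pairs:
            acc.setdefault(str(probe), [])
            if str(gene) not in acc[str(probe)]:
                acc[str(probe)].append(str(gene))
        return cls({p: tuple(gs) for p, gs in acc.items()})

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProbeMap":
        frame = pd.read_csv(path, sep="\t", dtype=str, header=None,
                            names=["probe_id", "gene_id"], comment="#")
        return cls.from_pairs(frame.itertuples(index=False, name=None))

    def genes_for(self, probe: str) -> tuple[str, ...]:
        return self.mapping.get(probe, ())


def collapse_probes(m: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Aggregate a probe-level matrix to gene level.

    Probes mapping to zero or multiple genes are dropped.  When several
    probes map to one gene, the gene's value is the arithmetic mean of the
    probe values, per sample.  Output genes are sorted by gene ID.
    """
    if not probe_map.mapping:
        raise MatrixValidationError("probe map is empty")
    probe_to_gene = {
        p: gs[0] for p, gs in probe_map.mapping.items() if len(gs) == 1
    }
    keep = [p for p in m.gene_ids if p in probe_to_gene]
    if not keep:
        raise MatrixValidationError("no probe maps to exactly one gene")
    sub = m.data.loc[keep]
    genes = pd.Index([probe_to_gene[p] for p in keep], name="gene_id")
    collapsed = sub.groupby(genes).mean().sort_index()
    return ExpressionMatrix(collapsed)


# ---------------------------------------------------------------------------
# Paired FF / FFPE cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedCohort:
    """An FF matrix and an FFPE matrix with a 1:1 sample pairing.

    The two matrices must carry the identical gene list in identical
    order; the pairing is a bijection between a subset of FF samples and a
    subset of FFPE samples (in this study's design, same-patient pairs).
    """

    ff: ExpressionMatrix
    ffpe: ExpressionMatrix
    pairing: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self):
        if self.ff.gene_ids != self.ffpe.gene_ids:
            raise MatrixValidationError(
                "FF and FFPE matrices must share an identical gene list"
            )
        pairing = tuple((str(a), str(b)) for a, b in self.pairing)
        object.__setattr__(self, "pairing", pairing)
        ff_ids = [a for a, _ in pairing]
        ffpe_ids = [b for _, b in pairing]
        if len(set(ff_ids)) != len(ff_ids) or len(set(ffpe_ids)) != len(ffpe_ids):
            raise MatrixValidationError("pairing must be a bijection")
        ff_known = set(self.ff.sample_ids)
        ffpe_known = set(self.ffpe.sample_ids)
        for a, b in pairing:
            if a not in ff_known:
                raise MatrixValidationError(f"unknown FF sample in pairing: {a!r}")
            if b not in ffpe_known:
                raise MatrixValidationError(f"unknown FFPE sample in pairing: {b!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def gene_ids(self) -> list[str]:
        return self.ff.gene_ids

    def iter_pairs(self):
        """Yield (ff_id, ffpe_id, ff_values, ffpe_values) per pair."""
        for a, b in self.pairing:
            yield a, b, self.ff.sample(a).to_numpy(), self.ffpe.sample(b).to_numpy()


def read_pairing(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV of (ff_sample_id, ffpe_sample_id)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise MatrixParseError(f"{path}: pairing file needs two columns")
    return [(str(a), str(b)) for a, b in frame.iloc[:, :2].itertuples(index=False, name=None)]


def write_pairing(pairing: Sequence[tuple[str, str]], path: str | Path) -> None:
    frame = pd.DataFrame(pairing, columns=["ff_sample_id", "ffpe_sample_id"])
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def drop_allzero_genes(cohort: PairedCohort) -> PairedCohort:
    """Remove genes whose value is zero in every FF sample AND every FFPE
    sample of the cohort; survivors keep their order.  Idempotent."""
    zero_ff = (cohort.ff.values == 0).all(axis=1)
    zero_ffpe = (cohort.ffpe.values == 0).all(axis=1)
    keep = ~(zero_ff & zero_ffpe)
    genes = [g for g, k in zip(cohort.ff.gene_ids, keep) if k]
    return PairedCohort(
        ff=cohort.ff.subset_genes(genes),
        ffpe=cohort.ffpe.subset_genes(genes),
        pairing=cohort.pairing,
    )


def drop_allzero_genes_matrix(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-matrix variant: drop genes that are zero in every sample."""
    keep = ~(m.values == 0).all(axis=1)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return m.subset_genes(genes)
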