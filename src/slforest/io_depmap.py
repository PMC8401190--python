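"""Readers and writers for DepMap-style omics matrices and mutation call tables.

All matrices are cell-line x gene CSVs whose first column holds the sample
identifier and whose remaining headers are gene labels, optionally of the
form ``"SYMBOL (ENTREZID)"``.  Loaded matrices are carried through the
pipeline as :class:`OmicsMatrix` objects wrapping a pandas DataFrame
(rows = samples, columns = genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("dependency", "expression", "mutation_binary")

DEFAULT_TRUTHY = ("true", "t", "yes", "y", "1")
DEFAULT_NA = ("", "NA", "NaN", "nan", "N/A", "null", "None")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class Dialect:
    """Column-mapping configuration for the CSV inputs.

    ``sample_col``/``gene_col``/... apply to the mutation call table; the
    matrix reader only uses ``na_values``.  Evidence columns may be declared
    absent by setting them to ``None``.
    """

    sample_col: str = "sample_id"
    gene_col: str = "gene"
    coding_score_col: str | None = "coding_score"
    damaging_col: str | None = "damaging"
    hotspot_col: str | None = "hotspot"
    na_values: tuple[str, ...] = DEFAULT_NA
    truthy: tuple[str, ...] = DEFAULT_TRUTHY


@dataclass
class OmicsMatrix:
    """A cell-line x gene numeric matrix of one kind.

    Invariants: unique sample and gene identifiers, shape consistency, and
    for ``mutation_binary`` all values in {0, 1}.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise DataError(f"unknown matrix kind {self.kind!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise DataError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise DataError(f"duplicate gene ids: {dups}")
        if self.kind == "mutation_binary":
            vals = self.data.to_numpy()
            if not np.isin(vals[~np.isnan(vals)], (0.0, 1.0)).all():
                raise DataError("mutation_binary matrix contains values outside {0,1}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, gene: str) -> pd.Series:
        return self.data[gene]


@dataclass
class MutationCallTable:
    """Long-format mutation calls with per-call pathogenicity evidence."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("sample_id", "gene_id", "coding_score", "damaging_flag", "hotspot_flag")

    def __post_init__(self) -> None:
        if self.records.empty and not len(self.records.columns):
            self.records = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise DataError(f"mutation call table missing columns: {sorted(missing)}")
        scores = self.records["coding_score"]
        bad = scores.dropna()
        if len(bad) and ((bad < 0) | (bad > 1)).any():
            raise DataError("coding_score values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.records)


def normalize_gene_label(label: str) -> str:
    """Strip a trailing ``" (ENTREZID)"`` annotation from a gene header."""
    return str(label).split(" (")[0].strip()


def read_omics_matrix(path, kind: str, dialect: Dialect | None = None) -> OmicsMatrix:
    """Read a samples x genes CSV into an :class:`OmicsMatrix`.

    Gene headers are normalized to bare symbols; a collision after
    normalization is an error naming the offending symbols.  All-missing
    columns are dropped (with a log message).  Non-numeric cells raise
    :class:`DataError` with their location.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(
        path, index_col=0, dtype=str, keep_default_na=False,
        na_values=list(dialect.na_values),
    )
    raw.index = raw.index.astype(str)
    genes = [normalize_gene_label(c) for c in raw.columns]
    counts = pd.Series(genes).value_counts()
    collided = sorted(counts[counts > 1].index)
    if collided:
        raise DataError(f"duplicate gene symbols after normalization: {collided}")
    raw.columns = genes

    def _parse(col: pd.Series) -> pd.Series:
        try:
            return pd.to_numeric(col)
        except (ValueError, TypeError):
            for row, v in col.items():
                if v is not None and not pd.isna(v):
                    try:
                        float(v)
                    except ValueError:
                        raise DataError(
                            f"non-numeric cell at row {row!r}, column {col.name!r}: {v!r}"
                        ) from None
            raise  # pragma: no cover

    data = raw.apply(_parse)
    all_missing = [g for g in data.columns if data[g].isna().all()]
    if all_missing:
        logger.warning("dropping %d all-missing columns: %s", len(all_missing), all_missing[:10])
        data = data.drop(columns=all_missing)
    return OmicsMatrix(data=data, kind=kind)


def write_omics_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix in the same CSV dialect :func:`read_omics_matrix` reads."""
    out = matrix.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_mutation_calls(path, dialect: Dialect | None = None) -> MutationCallTable:
    """Read a MAF-like CSV of mutation calls.

    Evidence columns declared ``None`` in the dialect yield missing scores /
    false flags.  Flags are parsed from the dialect's truthy strings
    (case-insensitive); anything else is false.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=list(dialect.na_values))
    for col in (dialect.sample_col, dialect.gene_col):
        if col not in raw.columns:
            raise DataError(f"mutation call table missing mandatory column {col!r}")

    truthy = {t.lower() for t in dialect.truthy}

    def _flag(colname: str | None) -> pd.Series:
        if colname is None or colname not in raw.columns:
            return pd.Series(False, index=raw.index)
        return raw[colname].map(lambda v: str(v).strip().lower() in truthy if pd.notna(v) else False)

    if dialect.coding_score_col is not None and dialect.coding_score_col in raw.columns:
        scores = pd.to_numeric(raw[dialect.coding_score_col], errors="coerce")
    else:
        scores = pd.Series(np.nan, index=raw.index)

    records = pd.DataFrame(
        {
            "sample_id": raw[dialect.sample_col].astype(str),
            "gene_id": raw[dialect.gene_col].astype(str),
            "coding_score": scores,
            "damaging_flag": _flag(dialect.damaging_col),
            "hotspot_flag": _flag(dialect.hotspot_col),
        }
    )
    return MutationCallTable(records=records)


def align_samples(*matrices: OmicsMatrix) -> tuple[OmicsMatrix, ...]:
    """Restrict matrices to their common samples, in a common stable order.

    Order follows the first matrix's sample order.  Raises on an empty
    intersection.
    """
    if not matrices:
        raise ValueError("align_samples requires at least one matrix")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise DataError("no samples shared across the input matrices")
    order = [s for s in matrices[0].sample_ids if s in common]
    logger.info("aligned matrices on %d common samples", len(order))
    return tuple(OmicsMatrix(data=m.data.loc[order], kind=m.kind) for m in matrices)
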