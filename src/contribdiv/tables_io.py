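"""Reading, validating, writing and interconverting the input table formats.

Three table layouts are supported:

* wide taxon abundance tables (taxa x samples, TSV),
* wide function copy-number tables (taxa x functions, TSV),
* long "contributional" tables with one row per (sample, function, taxon)
  combination, as emitted by stratified functional profilers. Two header
  dialects are recognised: ``generic`` (columns ``sample``, ``func``,
  ``taxon``, ``taxon_abun`` and optionally ``genome_function_count``) and
  ``picrust2`` (same, but the function column is named ``function``; extra
  columns are ignored).

All readers accept plain or gzip-compressed files (sniffed from the
extension by pandas). Values must be non-negative; duplicated labels are
rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "TaxonAbundanceTable",
    "FunctionCopyNumberTable",
    "ContributionalTable",
    "read_abundance_table",
    "read_copy_number_table",
    "read_contrib_table",
    "contrib_to_wide",
    "wide_to_contrib",
]

#: canonical long-format column names, in order
CONTRIB_COLUMNS = ("sample", "func", "taxon", "taxon_abun")
COPY_NUMBER_COLUMN = "genome_function_count"

#: per-dialect mapping {file column -> canonical column}
_DIALECTS = {
    "generic": {
        "sample": "sample",
        "func": "func",
        "taxon": "taxon",
        "taxon_abun": "taxon_abun",
        COPY_NUMBER_COLUMN: COPY_NUMBER_COLUMN,
    },
    "picrust2": {
        "sample": "sample",
        "function": "func",
        "taxon": "taxon",
        "taxon_abun": "taxon_abun",
        COPY_NUMBER_COLUMN: COPY_NUMBER_COLUMN,
    },
}


def _check_matrix(df: pd.DataFrame, kind: str, col_kind: str) -> None:
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValidationError(f"{kind} table is empty")
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise ValidationError(f"duplicate taxon labels in {kind} table: {dup_rows}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise ValidationError(
            f"duplicate {col_kind} labels in {kind} table: {dup_cols}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise ValidationError(
            f"non-numeric values in {kind} table columns: {list(bad)}"
        )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"missing value in {kind} table at "
            f"(taxon={df.index[r]!r}, {col_kind}={df.columns[c]!r})"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative value {values[r, c]} in {kind} table at "
            f"(taxon={df.index[r]!r}, {col_kind}={df.columns[c]!r})"
        )


@dataclass(frozen=True)
class TaxonAbundanceTable:
    """Taxa x samples matrix of non-negative abundances (unit-agnostic)."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_matrix(self.data, "abundance", "sample")

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        self.data.to_csv(path, sep=delimiter, index_label="taxon")

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonAbundanceTable) and self.data.equals(other.data)


@dataclass(frozen=True)
class FunctionCopyNumberTable:
    """Taxa x functions matrix of non-negative gene copy numbers."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_matrix(self.data, "copy-number", "function")

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def function_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        self.data.to_csv(path, sep=delimiter, index_label="taxon")

    def __eq__(self, other) -> bool:
        return isinstance(other, FunctionCopyNumberTable) and self.data.equals(
            other.data
        )


@dataclass(frozen=True)
class ContributionalTable:
    """Long records linking (sample, function, taxon) to abundance.

    ``data`` holds the canonical columns ``sample``, ``func``, ``taxon``,
    ``taxon_abun`` and, when copy-number information is available,
    ``genome_function_count``. The (sample, func, taxon) triples are unique.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CONTRIB_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(
                f"contributional table missing required columns: {missing}"
            )
        dup = self.data.duplicated(subset=["sample", "func", "taxon"])
        if dup.any():
            first = self.data.loc[dup, ["sample", "func", "taxon"]].iloc[0]
            raise ValidationError(
                "duplicate (sample, function, taxon) triple: "
                f"({first['sample']!r}, {first['func']!r}, {first['taxon']!r})"
            )
        if (self.data["taxon_abun"].to_numpy() < 0).any():
            raise ValidationError("negative taxon_abun in contributional table")
        if self.has_copy_number and (
            self.data[COPY_NUMBER_COLUMN].to_numpy() < 0
        ).any():
            raise ValidationError("negative copy number in contributional table")

    @property
    def has_copy_number(self) -> bool:
        return COPY_NUMBER_COLUMN in self.data.columns

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        cols = list(CONTRIB_COLUMNS) + (
            [COPY_NUMBER_COLUMN] if self.has_copy_number else []
        )
        self.data[cols].to_csv(path, sep=delimiter, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, ContributionalTable) and self.data.equals(other.data)


def _read_wide(path, delimiter: str, col_kind: str) -> pd.DataFrame:
    try:
        # pandas de-duplicates repeated header names, so check the raw header
        raw = pd.read_csv(path, sep=delimiter, header=None, nrows=1, dtype=str)
        header = raw.iloc[0].tolist()[1:]
        dups = sorted({c for c in header if header.count(c) > 1})
        if dups:
            raise ValidationError(f"duplicate {col_kind} labels in header: {dups}")
        df = pd.read_csv(
            path, sep=delimiter, index_col=0, header=0,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"could not parse table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def read_abundance_table(path, delimiter: str = "\t") -> TaxonAbundanceTable:
    """Read a wide taxa x samples abundance TSV.

    The first column holds taxon labels; the header row holds sample ids
    (the first header cell is ignored). Gzip input is transparently
    supported.
    """
    return TaxonAbundanceTable(_read_wide(path, delimiter, "sample"))


def read_copy_number_table(path, delimiter: str = "\t") -> FunctionCopyNumberTable:
    """Read a wide taxa x functions copy-number TSV."""
    return FunctionCopyNumberTable(_read_wide(path, delimiter, "function"))


def read_contrib_table(
    path, dialect: str = "generic", delimiter: str = "\t"
) -> ContributionalTable:
    """Read a long contributional table in the given header dialect.

    Returns canonical column names regardless of dialect; columns outside
    the dialect mapping are dropped.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(
            f"unknown dialect {dialect!r}; available: {sorted(_DIALECTS)}"
        )
    mapping = _DIALECTS[dialect]
    try:
        df = pd.read_csv(
            path, sep=delimiter, header=0, float_precision="round_trip"
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"could not parse table {path}: {exc}") from exc
    required = [src for src, dst in mapping.items() if dst in CONTRIB_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"contributional table ({dialect} dialect) missing columns: {missing}"
        )
    keep = [c for c in mapping if c in df.columns]
    df = df[keep].rename(columns=mapping)
    for col in ("sample", "func", "taxon"):
        df[col] = df[col].astype(str)
    return ContributionalTable(df.reset_index(drop=True))


def contrib_to_wide(
    ct: ContributionalTable,
) -> tuple[TaxonAbundanceTable, FunctionCopyNumberTable]:
    """Pivot a contributional table into wide abundance and copy-number tables.

    A taxon's abundance must be identical wherever it appears within a
    sample (it is repeated across function records); conflicting values are
    an error. Cells never observed are 0. When the copy-number column is
    absent, observed (taxon, function) pairs get copy number 1 (presence).
    """
    if len(ct) == 0:
        raise ValidationError("contributional table is empty")
    df = ct.data
    n_distinct = df.groupby(["taxon", "sample"])["taxon_abun"].nunique()
    conflicts = n_distinct[n_distinct > 1]
    if len(conflicts):
        taxon, sample = conflicts.index[0]
        raise ValidationError(
            f"conflicting abundance values for taxon {taxon!r} in sample "
            f"{sample!r} across contributional records"
        )
    abund = (
        df.groupby(["taxon", "sample"])["taxon_abun"]
        .first()
        .unstack(fill_value=0.0)
        .astype(float)
    )
    abund = abund.rename_axis(index=None, columns=None)
    cn_col = (
        df[COPY_NUMBER_COLUMN]
        if ct.has_copy_number
        else pd.Series(1.0, index=df.index)
    )
    cn = (
        df.assign(_cn=cn_col)
        .groupby(["taxon", "func"])["_cn"]
        .max()
        .unstack(fill_value=0.0)
        .astype(float)
    )
    cn = cn.rename_axis(index=None, columns=None)
    return TaxonAbundanceTable(abund), FunctionCopyNumberTable(cn)


def wide_to_contrib(
    abund: TaxonAbundanceTable, cn: FunctionCopyNumberTable
) -> ContributionalTable:
    """Combine wide tables into a long contributional table.

    One record is emitted per (sample, function, taxon) where the taxon has
    abundance > 0 in the sample AND copy number > 0 for the function. Only
    taxa present in both tables are considered; a label mismatch warns, zero
    overlap is an error.
    """
    shared = [t for t in abund.taxon_ids if t in set(cn.taxon_ids)]
    if not shared:
        raise ValidationError(
            "no overlap between abundance-table and copy-number-table taxa"
        )
    n_only_abund = len(abund.taxon_ids) - len(shared)
    n_only_cn = len(set(cn.taxon_ids) - set(shared))
    if n_only_abund or n_only_cn:
        warnings.warn(
            f"taxon label mismatch: {n_only_abund} taxa only in the abundance "
            f"table, {n_only_cn} only in the copy-number table; restricting to "
            f"the {len(shared)} shared taxa",
            stacklevel=2,
        )
    a = abund.data.loc[shared]
    c = cn.data.loc[shared]
    records = []
    for func in c.columns:
        contributors = c.index[c[func].to_numpy() > 0]
        for taxon in contributors:
            row = a.loc[taxon]
            for sample in a.columns[row.to_numpy() > 0]:
                records.append(
                    (sample, func, taxon, float(row[sample]), float(c.at[taxon, func]))
                )
    df = pd.DataFrame(
        records, columns=list(CONTRIB_COLUMNS) + [COPY_NUMBER_COLUMN]
    )
    return ContributionalTable(df)
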