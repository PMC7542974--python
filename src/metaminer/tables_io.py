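"""Tabular data model and text I/O.

The central container is :class:`PeakTable`, a samples x variables intensity
matrix backed by a pandas DataFrame.  All files are tab-delimited UTF-8 text
with a header row and a first column of row identifiers; missing values may
be written as an empty cell, ``NA`` or ``NaN`` (case-insensitive) and are
always written back out as empty cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "SampleMetadata",
    "read_peak_table",
    "write_peak_table",
    "read_sample_metadata",
    "write_result_table",
    "read_result_table",
    "merge_tables",
    "retrieve_rows",
]

_MISSING_TOKENS = {"", "na", "nan"}


@dataclass
class PeakTable:
    """Samples x variables intensity matrix.

    Attributes
    ----------
    data:
        DataFrame with sample identifiers as the index and variable
        identifiers as the columns.  Values are floats; missing entries are
        NaN.
    variable_meta:
        Optional per-variable metadata (``mz`` in Dalton, ``rt`` in seconds,
        ``annotation``, ``is_ratio`` ...), indexed by variable id.
    log_transformed:
        Provenance flag set by the log transform so downstream fold changes
        can be computed on the original scale.
    """

    data: pd.DataFrame
    variable_meta: pd.DataFrame | None = None
    log_transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate variable identifiers: {dups}")
        self.data = self.data.astype(float)
        self.data.index = idx.astype(str)
        self.data.columns = cols.astype(str)
        if self.variable_meta is not None:
            self.variable_meta = self.variable_meta.reindex(self.data.columns)

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def transpose(self) -> "PeakTable":
        """Swap the roles of samples and variables."""
        return PeakTable(self.data.T.copy(), None, self.log_transformed)

    def copy(self) -> "PeakTable":
        meta = None if self.variable_meta is None else self.variable_meta.copy()
        return PeakTable(self.data.copy(), meta, self.log_transformed)

    def mz(self) -> pd.Series | None:
        if self.variable_meta is not None and "mz" in self.variable_meta:
            return self.variable_meta["mz"]
        return None

    def rt(self) -> pd.Series | None:
        if self.variable_meta is not None and "rt" in self.variable_meta:
            return self.variable_meta["rt"]
        return None


@dataclass
class SampleMetadata:
    """Per-sample design information: group label, injection order, QC flag
    and optional numeric confounders."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in metadata")
        self.frame.index = self.frame.index.astype(str)
        if "group" not in self.frame.columns:
            raise ValueError("metadata requires a 'group' column")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def groups(self, samples: Sequence[str] | None = None) -> pd.Series:
        g = self.frame["group"].astype(str)
        return g.loc[list(samples)] if samples is not None else g

    def group_levels(self, samples: Sequence[str] | None = None) -> list[str]:
        return sorted(self.groups(samples).unique())

    def injection_order(self) -> pd.Series | None:
        if "injection_order" in self.frame.columns:
            return self.frame["injection_order"].astype(float)
        return None

    def is_qc(self) -> pd.Series:
        if "is_qc" in self.frame.columns:
            col = self.frame["is_qc"]
            if col.dtype == object:
                return col.astype(str).str.lower().isin({"1", "true", "yes", "qc"})
            return col.astype(bool)
        return pd.Series(False, index=self.frame.index)

    def confounders(self) -> pd.DataFrame:
        reserved = {"group", "injection_order", "is_qc"}
        cols = [c for c in self.frame.columns if c not in reserved]
        return self.frame[cols].astype(float)

    def aligned_to(self, table: PeakTable) -> "SampleMetadata":
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise ValueError(f"metadata lacks samples: {sorted(missing)}")
        return SampleMetadata(self.frame.loc[table.sample_ids].copy())


# -- parsing helpers -------------------------------------------------------

def _parse_cell(text: str, row: str, col: str) -> float:
    stripped = text.strip()
    if stripped.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(stripped)
    except ValueError:
        raise ValueError(
            f"non-numeric value {text!r} at row {row!r}, column {col!r}"
        ) from None


def read_peak_table(
    path,
    orientation: Literal["samples_in_rows", "variables_in_rows"] = "samples_in_rows",
) -> PeakTable:
    """Read a tab-delimited intensity table.

    The file must have a header row and a first column of identifiers.  The
    returned table is always in canonical samples x variables orientation;
    ``orientation`` states how the *file* is laid out.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    raw.index = raw.index.astype(str)
    parsed = pd.DataFrame(
        [
            [_parse_cell(raw.iat[i, j], str(raw.index[i]), str(raw.columns[j]))
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
    )
    table = PeakTable(parsed)
    if orientation == "variables_in_rows":
        table = table.transpose()
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return table


def write_peak_table(table: PeakTable, path) -> None:
    """Write a PeakTable as tab-delimited text (samples in rows)."""
    table.data.to_csv(path, sep="\t", na_rep="", float_format="%.15g",
                      index_label="sample_id")


def read_sample_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(frame)


def write_result_table(result: pd.DataFrame, path) -> None:
    """Write a result table (one row per analyzed unit) as tab-delimited text.

    Values round-trip to 12 significant digits; magnitudes >= 1e-4 are
    written in positional notation.
    """
    if result.empty:
        raise ValueError("refusing to write an empty result table")
    out = result.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", na_rep="", index_label=out.index.name or "id")


def _format_float(x: float) -> str:
    if pd.isna(x):
        return ""
    if x == 0 or 1e-4 <= abs(x) < 1e16:
        s = f"{x:.12f}" if abs(x) < 1 else f"{x:.12g}"
        if "." in s and "e" not in s and "E" not in s:
            s = s.rstrip("0").rstrip(".")
        return s or "0"
    return f"{x:.12g}"


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- table algebra ---------------------------------------------------------

def merge_tables(
    a: PeakTable, b: PeakTable, axis: Literal["samples", "variables"] = "variables"
) -> PeakTable:
    """Concatenate two tables along samples or variables.

    The shared axis is aligned by identifier and must be identical as a set;
    identifier collisions on the grown axis are resolved by suffixing the
    second table's ids with ``_2`` (then ``_3`` ...).
    """
    if axis == "variables":
        if b.n_variables == 0:
            return a.copy()
        shared_a, shared_b = set(a.sample_ids), set(b.sample_ids)
        if shared_a != shared_b:
            raise ValueError(
                "sample identifiers differ between tables: "
                f"{sorted(shared_a ^ shared_b)}"
            )
        bd = b.data.loc[a.sample_ids]
        new_cols = _dedupe(a.variable_ids, list(bd.columns))
        bd = bd.set_axis(new_cols, axis=1)
        merged = pd.concat([a.data, bd], axis=1)
        meta = _merge_meta(a, b, dict(zip(b.variable_ids, new_cols)))
        return PeakTable(merged, meta, a.log_transformed)
    if axis == "samples":
        if b.n_samples == 0:
            return a.copy()
        if set(a.variable_ids) != set(b.variable_ids):
            raise ValueError(
                "variable identifiers differ between tables: "
                f"{sorted(set(a.variable_ids) ^ set(b.variable_ids))}"
            )
        bd = b.data[a.variable_ids]
        new_rows = _dedupe(a.sample_ids, list(bd.index))
        bd = bd.set_axis(new_rows, axis=0)
        merged = pd.concat([a.data, bd], axis=0)
        return PeakTable(merged, a.variable_meta, a.log_transformed)
    raise ValueError(f"unknown axis {axis!r}")


def _dedupe(existing: list[str], incoming: list[str]) -> list[str]:
    taken = set(existing)
    out: list[str] = []
    for name in incoming:
        candidate, k = name, 2
        while candidate in taken:
            candidate = f"{name}_{k}"
            k += 1
        taken.add(candidate)
        out.append(candidate)
    return out


def _merge_meta(a: PeakTable, b: PeakTable, rename: dict) -> pd.DataFrame | None:
    if a.variable_meta is None and b.variable_meta is None:
        return None
    parts = []
    if a.variable_meta is not None:
        parts.append(a.variable_meta)
    else:
        parts.append(pd.DataFrame(index=a.variable_ids))
    if b.variable_meta is not None:
        parts.append(b.variable_meta.rename(index=rename))
    else:
        parts.append(pd.DataFrame(index=list(rename.values())))
    return pd.concat(parts, axis=0)


def retrieve_rows(table: PeakTable, ids: Iterable[str]) -> PeakTable:
    """Subset samples by identifier, preserving the requested order.

    Unknown identifiers are reported with a warning, never silently dropped.
    """
    ids = [str(i) for i in ids]
    known = [i for i in ids if i in table.data.index]
    unknown = [i for i in ids if i not in table.data.index]
    if unknown:
        warnings.warn(f"unknown sample ids skipped: {unknown}", stacklevel=2)
    return PeakTable(table.data.loc[known].copy(), table.variable_meta,
                     table.log_transformed)
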