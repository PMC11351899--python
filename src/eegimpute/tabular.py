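"""Tabular dataset container and reorganisation primitives.

The whole pipeline operates on one currency: a rectangular numeric table
with an explicit missingness mask and per-row integer identifiers.  Missing
cells are stored as NaN; the boolean ``mask`` (True = missing) is kept in
lock-step with the values and is the authoritative record of which cells
were absent in the input, which matters once cells have been imputed.

Row identifiers are assigned once, at read/creation time, and travel with
the rows through every reordering so the original row order can always be
restored at the end of the imputation pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MISSING_MARKERS = ("", "na", "nan", "null")


class TableFormatError(ValueError):
    """Raised when a delimited file cannot be interpreted as a numeric table."""


@dataclass
class TabularDataset:
    """Numeric grid + column names + row IDs + missingness mask.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols), dtype float
        Cell values; missing cells hold NaN.
    col_names : list of str
        Unique column names, one per column.
    row_ids : ndarray of int
        Unique identifier per row; ``0..n_rows-1`` at creation time.
    mask : ndarray of bool, same shape as ``values``
        True where the cell is missing.
    """

    values: np.ndarray
    col_names: list[str]
    row_ids: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        self.col_names = list(self.col_names)
        self.row_ids = np.asarray(self.row_ids, dtype=int)
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        n_rows, n_cols = self.values.shape
        if len(self.col_names) != n_cols:
            raise ValueError("col_names length does not match column count")
        if len(set(self.col_names)) != n_cols:
            raise ValueError("col_names must be unique")
        if self.row_ids.shape != (n_rows,):
            raise ValueError("row_ids length does not match row count")
        if len(np.unique(self.row_ids)) != n_rows:
            raise ValueError("row_ids must be unique")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if not np.array_equal(self.mask, np.isnan(self.values)):
            raise ValueError("mask must be True exactly where values are NaN")

    # -- basic introspection -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def col_index(self, name: str) -> int:
        try:
            return self.col_names.index(name)
        except ValueError:
            raise KeyError(f"unknown column {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.col_index(name)]

    def missing_counts(self) -> dict[str, int]:
        """Missing-cell count per column name."""
        per_col = self.mask.sum(axis=0)
        return {name: int(per_col[j]) for j, name in enumerate(self.col_names)}

    def complete_row_index(self) -> np.ndarray:
        """Boolean index of rows with no missing cell in any column."""
        return ~self.mask.any(axis=1)

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            self.values.copy(), list(self.col_names), self.row_ids.copy(),
            self.mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.col_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, row_ids: np.ndarray | None = None
                   ) -> "TabularDataset":
        values = frame.to_numpy(dtype=float)
        if row_ids is None:
            row_ids = np.arange(len(frame))
        return cls(values, list(frame.columns), row_ids)


@dataclass(frozen=True)
class ColumnPartition:
    """Split of feature columns and rows by completeness.

    ``complete_cols`` have zero missing cells, ``incomplete_cols`` at least
    one; ``complete_row_ids`` identifies rows that are fully observed across
    every column of the table (those rows are the training pool of the
    imputation loop).
    """

    complete_cols: tuple[str, ...]
    incomplete_cols: tuple[str, ...]
    complete_row_ids: tuple[int, ...]


def read_table(path, missing_markers=DEFAULT_MISSING_MARKERS) -> TabularDataset:
    """Read a delimited text file (header required) into a TabularDataset.

    A cell is marked missing when, stripped and lower-cased, it equals one of
    ``missing_markers``.  Every other cell must parse as a real number.
    Row IDs are assigned 0..n-1 in file order.
    """
    markers = {str(m).strip().lower() for m in missing_markers}
    if hasattr(path, "read"):  # file-like: buffer so we can scan twice
        text = path.read()
        opener = lambda: io.StringIO(text)  # noqa: E731
    else:
        opener = lambda: path  # noqa: E731
    try:
        # header read separately: pandas silently renames duplicate headers
        header = pd.read_csv(opener(), dtype=str, header=None, nrows=1,
                             keep_default_na=False).iloc[0].tolist()
        raw = pd.read_csv(opener(), dtype=str, keep_default_na=False,
                          skip_blank_lines=False)
    except FileNotFoundError:
        raise
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    if len(set(header)) != len(header):
        raise TableFormatError(f"duplicate header names in {path}")
    raw.columns = header
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col].astype(str).str.strip()
        is_missing = cells.str.lower().isin(markers)
        parsed = pd.to_numeric(cells.where(~is_missing), errors="coerce")
        bad = parsed.isna() & ~is_missing
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise TableFormatError(
                f"non-numeric cell {cells[bad].iloc[0]!r} in column {col!r} "
                f"at line {line} of {path}")
        values[:, j] = parsed.to_numpy(dtype=float)
    return TabularDataset(values, list(raw.columns), np.arange(len(raw)))


def write_table(ds: TabularDataset, path, id_column: str | None = None
                ) -> None:
    """Write a TabularDataset as CSV; missing cells become empty fields.

    Row IDs are internal bookkeeping and are not persisted unless
    ``id_column`` names a column to hold them (prepended).
    """
    frame = ds.to_frame()
    if id_column is not None:
        frame.insert(0, id_column, ds.row_ids)
    frame.to_csv(path, index=False, na_rep="")


def write_table_string(ds: TabularDataset) -> str:
    buf = io.StringIO()
    write_table(ds, buf)
    return buf.getvalue()


def partition_columns(ds: TabularDataset, feature_cols: list[str]
                      ) -> ColumnPartition:
    """Classify feature columns by completeness and find fully observed rows."""
    for name in feature_cols:
        ds.col_index(name)
    counts = ds.missing_counts()
    complete = tuple(c for c in feature_cols if counts[c] == 0)
    incomplete = tuple(c for c in feature_cols if counts[c] > 0)
    complete_rows = tuple(int(i) for i in ds.row_ids[ds.complete_row_index()])
    return ColumnPartition(complete, incomplete, complete_rows)


def partition_and_reorder(ds: TabularDataset, feature_cols: list[str],
                          id_like_cols: list[str] = ()
                          ) -> tuple[TabularDataset, ColumnPartition]:
    """Move complete feature columns left and complete rows to the top.

    Both reorderings are stable: ties keep their input relative order.
    ``id_like_cols`` (e.g. Timestamp) are carried along in front of the
    feature block and are never candidates for imputation.  Row IDs travel
    with their rows, so :func:`restore_order` undoes the row permutation.
    """
    part = partition_columns(ds, feature_cols)
    other = [c for c in ds.col_names
             if c not in feature_cols and c not in id_like_cols]
    new_cols = (list(id_like_cols) + list(part.complete_cols)
                + list(part.incomplete_cols) + other)
    col_perm = [ds.col_index(c) for c in new_cols]
    complete = ds.complete_row_index()
    row_perm = np.concatenate([np.flatnonzero(complete),
                               np.flatnonzero(~complete)])
    reordered = TabularDataset(
        ds.values[np.ix_(row_perm, col_perm)], new_cols,
        ds.row_ids[row_perm], ds.mask[np.ix_(row_perm, col_perm)])
    return reordered, part


def restore_order(ds: TabularDataset) -> TabularDataset:
    """Sort rows ascending by row ID, restoring the original sequence."""
    ids = ds.row_ids
    if not np.array_equal(np.sort(ids), np.arange(len(ids))):
        raise ValueError("row_ids are not a permutation of 0..n-1")
    order = np.argsort(ids)
    return TabularDataset(ds.values[order], list(ds.col_names),
                          ids[order], ds.mask[order])
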