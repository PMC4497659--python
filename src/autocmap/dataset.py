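"""Tabular dataset container and preprocessing.

The analyses in this package operate on a complete (no missing entries)
numeric table of P records × N variables.  Variables are mapped to network
nodes; records can take that role instead after :func:`transpose_records`.
Class membership (e.g. a diagnostic group) may be carried either as ordinary
0/1 indicator columns, as categorical per-record labels, or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CompletenessError, SchemaError

__all__ = ["Dataset", "load_dataset", "minmax_scale", "transpose_records"]


@dataclass(frozen=True)
class Dataset:
    """A complete numeric table with named variables and records.

    Parameters
    ----------
    values : pandas.DataFrame
        P×N numeric frame; index = record identifiers, columns = variable
        names.  Must contain no missing entries.
    class_labels : pandas.Series, optional
        Categorical label per record (aligned with ``values.index``).
    scaled : bool
        True when every entry is guaranteed to lie in [0, 1] because the
        table went through :func:`minmax_scale`.
    """

    values: pd.DataFrame
    class_labels: pd.Series | None = None
    scaled: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise CompletenessError("dataset contains missing values")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate variable names: {dups}")
        if v.index.duplicated().any():
            raise SchemaError("duplicate record identifiers")
        if not all(np.issubdtype(dt, np.number) for dt in v.dtypes):
            raise SchemaError("non-numeric column in dataset")
        if self.scaled:
            arr = v.to_numpy(float)
            if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
                raise ValueError("scaled dataset has entries outside [0, 1]")
        if self.class_labels is not None and not self.class_labels.index.equals(v.index):
            raise SchemaError("class_labels index does not match record ids")

    # -- convenience views ------------------------------------------------
    @property
    def variable_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def record_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def select(self, variables: Sequence[str]) -> "Dataset":
        """Sub-dataset restricted to the given variables (order preserved)."""
        missing = [v for v in variables if v not in self.values.columns]
        if missing:
            raise KeyError(f"unknown variables: {missing}")
        return replace(self, values=self.values.loc[:, list(variables)])

    def where_label(self, label: str) -> "Dataset":
        """Sub-dataset of the records carrying the given class label."""
        if self.class_labels is None:
            raise ValueError("dataset has no class labels")
        mask = (self.class_labels == label).to_numpy()
        if not mask.any():
            raise KeyError(f"no records labelled {label!r}")
        return Dataset(
            values=self.values.loc[mask],
            class_labels=self.class_labels.loc[mask],
            scaled=self.scaled,
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        if self.class_labels is not None:
            out.insert(len(out.columns), "__class__", self.class_labels)
        out.to_csv(path, index_label="record_id")


def load_dataset(
    path: str | Path,
    class_columns: Sequence[str] | None = None,
    label_from: str | None = None,
) -> Dataset:
    """Read a delimited text table into a :class:`Dataset`.

    The file must be rectangular with a header row; the first column is used
    as the record identifier.  ``class_columns`` names 0/1 indicator columns
    that stay in the table but also define categorical labels: each record is
    labelled by the indicator column that equals 1.  Alternatively
    ``label_from`` names a single indicator whose 1/0 value splits the
    records into ``label_from`` / ``not-label_from``.

    Raises
    ------
    SchemaError
        Empty file, duplicate variable names, or non-numeric cells.
    CompletenessError
        Any blank/missing cell — the methods here require complete data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header_line = fh.readline().strip()
    header = [h.strip() for h in header_line.split(",")][1:]
    if header and len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise SchemaError(f"duplicate variable names in header: {dups}")
    try:
        frame = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("empty file") from exc
    if frame.shape[1] == 0:
        raise SchemaError("table has no variable columns")
    frame.index.name = None
    for col in frame.columns:
        if frame[col].dtype == object:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if coerced.isna().any() and frame[col].notna().all():
                raise SchemaError(f"non-numeric values in column {col!r}")
            frame[col] = coerced
    labels = None
    if class_columns:
        missing = [c for c in class_columns if c not in frame.columns]
        if missing:
            raise SchemaError(f"declared class columns not in table: {missing}")
        sub = frame[list(class_columns)]
        if sub.isna().any().any():
            raise CompletenessError("missing values in class columns")
        labels = sub.idxmax(axis=1)
    return Dataset(values=frame, class_labels=labels)


def minmax_scale(ds: Dataset) -> Dataset:
    """Scale every variable independently into [0, 1] by (x−min)/(max−min).

    Constant variables map to all-zeros (the 0/0 case is guarded), which
    keeps every entry inside the unit interval without NaNs.  Idempotent on
    data already spanning exactly [0, 1] per variable.
    """
    arr = ds.to_numpy()
    lo = arr.min(axis=0)
    span = arr.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (arr - lo) / safe
    scaled[:, span == 0] = 0.0
    frame = pd.DataFrame(scaled, index=ds.values.index, columns=ds.values.columns)
    return Dataset(values=frame, class_labels=ds.class_labels, scaled=True)


def transpose_records(ds: Dataset) -> Dataset:
    """Swap the roles of records and variables.

    The returned dataset has the original record identifiers as variable
    names and vice versa; class labels do not survive (they described the
    original records, which are now variables).  The ``scaled`` flag is
    reset: scaling is a per-variable property and the variables changed.
    """
    return Dataset(values=ds.values.T.copy(), class_labels=None, scaled=False)
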