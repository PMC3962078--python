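"""Descriptor tables, selection masks, and their file formats.

Supported on-disk formats:

* the Dragon 6.0 export triplet — three plain-text files sharing a base
  name: descriptor values (whitespace/tab delimited, no header), descriptor
  names (one per line), and object/structure names (one per line);
* a canonical CSV with objects as rows: first column is the object name,
  an optional ``y`` column carries the modelled property, the remaining
  columns are descriptors;
* selection masks as JSON ``{"variable_names": ..., "mask": ..., "provenance": ...}``.

Missing descriptor values are represented by NaN throughout; any token in a
Dragon values file that does not parse as a number (``NA``, ``na``, ``-``,
...) becomes NaN on import.  Model-fitting operations reject tables that
still contain missing values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "SelectionMask",
    "import_dragon",
    "attach_property",
    "save_mask",
    "load_mask",
    "save_table",
    "load_table",
]


class DimensionMismatchError(ValueError):
    """Raised when files or arrays that must agree in shape do not."""


def _dedupe_names(names: Sequence[str]) -> list[str]:
    """Make names unique by appending ``_2``, ``_3``, ... to repeats in order."""
    seen: dict[str, int] = {}
    out: list[str] = []
    dupes = []
    for name in names:
        count = seen.get(name, 0) + 1
        seen[name] = count
        if count == 1:
            out.append(name)
        else:
            dupes.append(name)
            out.append(f"{name}_{count}")
    if dupes:
        warnings.warn(
            f"{len(dupes)} duplicate variable name(s) disambiguated with numeric "
            f"suffixes (first: {dupes[0]!r})",
            stacklevel=3,
        )
    return out


@dataclass
class DescriptorTable:
    """An n x m descriptor matrix with labels and an optional property vector.

    ``X`` holds descriptor values in their native units, one object per
    row; ``y`` (when attached) holds the modelled property, e.g. a GC
    retention index.  Missing entries in ``X`` are NaN.
    """

    X: np.ndarray
    variable_names: list[str]
    object_names: list[str]
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, m = self.X.shape
        self.variable_names = _dedupe_names([str(v) for v in self.variable_names])
        self.object_names = [str(o) for o in self.object_names]
        if len(self.object_names) != n:
            raise DimensionMismatchError(
                f"{len(self.object_names)} object names for {n} rows of X"
            )
        if len(self.variable_names) != m:
            raise DimensionMismatchError(
                f"{len(self.variable_names)} variable names for {m} columns of X"
            )
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (n,):
                raise DimensionMismatchError(
                    f"y has length {self.y.size}, expected {n}"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.X).any())

    def require_complete(self) -> None:
        if self.has_missing():
            bad = int(np.isnan(self.X).sum())
            raise ValueError(
                f"descriptor matrix contains {bad} missing value(s); "
                "remove or impute them before model fitting"
            )

    def require_y(self) -> np.ndarray:
        if self.y is None:
            raise ValueError("no property vector y attached to this table")
        return self.y

    def subset(self, mask: "SelectionMask | np.ndarray") -> "DescriptorTable":
        """Return the table restricted to the variables marked True in ``mask``."""
        sel = mask.mask if isinstance(mask, SelectionMask) else np.asarray(mask, bool)
        if sel.shape != (self.m,):
            raise DimensionMismatchError(
                f"mask length {sel.size} does not match m={self.m}"
            )
        if not sel.any():
            raise ValueError("selection mask retains no variables")
        return DescriptorTable(
            X=self.X[:, sel],
            variable_names=[v for v, s in zip(self.variable_names, sel) if s],
            object_names=list(self.object_names),
            y=None if self.y is None else self.y.copy(),
        )


@dataclass
class SelectionMask:
    """A positional boolean vector over the m variables of a table.

    ``provenance`` is a free-text record of the producing operator and its
    parameters, so that chained selections remain auditable.
    """

    mask: np.ndarray
    provenance: str = ""
    variable_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 1-D boolean vector")
        if self.variable_names is not None and len(self.variable_names) != self.mask.size:
            raise DimensionMismatchError("variable_names length does not match mask")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def __and__(self, other: "SelectionMask") -> "SelectionMask":
        if other.mask.size != self.mask.size:
            raise DimensionMismatchError("cannot AND masks of different length")
        return SelectionMask(
            mask=self.mask & other.mask,
            provenance=f"{self.provenance} AND {other.provenance}".strip(),
            variable_names=self.variable_names or other.variable_names,
        )


def _read_lines(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise IOError(f"file is empty: {path}")
    return lines


def import_dragon(
    values_path: str | Path,
    names_path: str | Path,
    objects_path: str | Path,
) -> DescriptorTable:
    """Import a Dragon 6.0 descriptor export (three text files).

    The values file is whitespace- or tab-delimited with no header; rows
    correspond, in order, to lines of the objects file and columns to lines
    of the names file.  Non-numeric tokens become NaN.  Returns a table
    without a property vector (attach one with :func:`attach_property`).
    """
    value_lines = _read_lines(values_path)
    names = _read_lines(names_path)
    objects = _read_lines(objects_path)

    rows: list[list[float]] = []
    width = None
    for i, line in enumerate(value_lines):
        tokens = line.replace("\t", " ").split()
        if width is None:
            width = len(tokens)
        elif len(tokens) != width:
            raise DimensionMismatchError(
                f"{values_path}: row {i + 1} has {len(tokens)} values, "
                f"row 1 has {width}"
            )
        row = []
        for tok in tokens:
            try:
                row.append(float(tok))
            except ValueError:
                row.append(np.nan)
        rows.append(row)

    if len(rows) != len(objects):
        raise DimensionMismatchError(
            f"{values_path} has {len(rows)} rows but {objects_path} "
            f"names {len(objects)} objects"
        )
    if width != len(names):
        raise DimensionMismatchError(
            f"{values_path} has {width} columns but {names_path} "
            f"names {len(names)} variables"
        )
    return DescriptorTable(
        X=np.array(rows, dtype=float),
        variable_names=names,
        object_names=objects,
    )


def attach_property(
    table: DescriptorTable,
    y_source: str | Path | Sequence[float] | np.ndarray,
) -> DescriptorTable:
    """Attach a property vector y to a table, from a vector or a text file.

    A file source may be a one-column text/CSV file, with or without a
    header line; y must be numeric, complete, and of length n.
    """
    if isinstance(y_source, (str, Path)):
        lines = _read_lines(y_source)
        try:
            float(lines[0])
        except ValueError:
            lines = lines[1:]  # header line
        y = np.array([float(ln.split(",")[0]) for ln in lines])
    else:
        y = np.asarray(y_source, dtype=float)
    if y.shape != (table.n,):
        raise DimensionMismatchError(
            f"y has length {y.size}, table has n={table.n} objects"
        )
    if np.isnan(y).any():
        raise ValueError("property vector y contains missing values")
    return replace(table, y=y)


def save_table(table: DescriptorTable, path: str | Path) -> None:
    """Write a table to the canonical CSV format (first column = object name)."""
    df = pd.DataFrame(table.X, columns=table.variable_names)
    if table.y is not None:
        df.insert(0, "y", table.y)
    df.insert(0, "object", table.object_names)
    df.to_csv(path, index=False)


def load_table(path: str | Path) -> DescriptorTable:
    """Read a table from the canonical CSV format written by :func:`save_table`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise IOError(f"{path}: expected at least an object column and one descriptor")
    objects = df.iloc[:, 0].astype(str).tolist()
    df = df.iloc[:, 1:]
    y = None
    if "y" in df.columns:
        y = df.pop("y").to_numpy(float)
    return DescriptorTable(
        X=df.to_numpy(float),
        variable_names=list(df.columns),
        object_names=objects,
        y=y,
    )


def save_mask(mask: SelectionMask, path: str | Path) -> None:
    """Serialize a selection mask (and its provenance) to JSON."""
    payload = {
        "mask": [bool(v) for v in mask.mask],
        "provenance": mask.provenance,
        "variable_names": mask.variable_names,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_mask(path: str | Path) -> SelectionMask:
    payload = json.loads(Path(path).read_text())
    return SelectionMask(
        mask=np.array(payload["mask"], dtype=bool),
        provenance=payload.get("provenance", ""),
        variable_names=payload.get("variable_names"),
    )
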