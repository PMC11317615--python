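"""Sample tables and normalization.

The whole pipeline operates on a :class:`DataMatrix`: an N x d table of
numeric samples with named variables.  Variables are standardized to zero
mean and unit variance before any kernel regression; the raw per-column
(mean, sd) pairs are retained so that reports can be mapped back to the
original units.

Variables may be grouped into named *cluster nodes* (see
:func:`chd.graph.merge_cluster`): a cluster enters candidate kernels
jointly and is never separated during pruning.  A plain table is the
special case where every node is a singleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "read_table", "normalize"]


@dataclass(frozen=True)
class DataMatrix:
    """An N x d numeric sample table with named variables.

    Parameters
    ----------
    values
        Array of shape (N, d); one column per variable.
    names
        Unique, non-empty variable names, one per column.
    center, scale
        Per-column mean and (population) standard deviation of the raw
        input, recorded by :func:`normalize`.  ``None`` for raw tables.
    groups
        Mapping node name -> tuple of member variable names.  Defaults to
        one singleton node per variable.
    """

    values: np.ndarray
    names: tuple[str, ...]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(names) != values.shape[1]:
            raise ValueError(
                f"{len(names)} names for {values.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        if any(not n for n in names):
            raise ValueError("variable names must be non-empty")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at row {r}, column {names[c]!r} "
                f"({len(bad)} bad cells in total)"
            )
        if not self.groups:
            object.__setattr__(
                self, "groups", {n: (n,) for n in names}
            )
        else:
            members = [v for vs in self.groups.values() for v in vs]
            if len(set(members)) != len(members):
                raise ValueError("cluster groups must be disjoint")
            unknown = set(members) - set(names)
            if unknown:
                raise ValueError(f"unknown variables in groups: {sorted(unknown)}")

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def nodes(self) -> tuple[str, ...]:
        """Names of the graph nodes (clusters count as one node)."""
        return tuple(self.groups)

    def columns_of(self, node: str) -> tuple[str, ...]:
        """Member variables of a node (itself, for a singleton)."""
        try:
            return self.groups[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None
        return self.values[:, j]

    def matrix(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        """Columns for the given variables, in the given order."""
        idx = [self.names.index(n) for n in names]
        return self.values[:, idx]

    @property
    def is_normalized(self) -> bool:
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0)
        return bool(np.all(np.abs(mu) < 1e-8) and np.all(np.abs(sd - 1) < 1e-8))

    # -- conversions ---------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))


def read_table(
    path: str | Path,
    fmt: str | None = None,
    header: bool = True,
) -> DataMatrix:
    """Read a CSV/TSV sample table (one column per variable) as a raw
    :class:`DataMatrix`.

    ``fmt`` is ``"csv"`` or ``"tsv"``; when omitted it is inferred from
    the file suffix (defaulting to CSV).  Without a header row, variables
    are named ``v1..vd``.  Ragged rows, non-numeric or missing cells and
    duplicate names are rejected with row/column diagnostics.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown table format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    if header:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().rstrip("\n").rstrip("\r")
        cols = [c.strip() for c in first.split(sep)]
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        if dupes:
            raise ValueError(f"{path}: duplicate column names {dupes}")
    df = pd.read_csv(path, sep=sep, header=0 if header else None)
    if not header:
        df.columns = [f"v{i + 1}" for i in range(df.shape[1])]
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.index[series.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing cell in column {col!r} "
                f"at row {int(bad[0])}"
            )
        df[col] = series
    return DataMatrix.from_dataframe(df)


def normalize(data: DataMatrix) -> DataMatrix:
    """Standardize every column to zero mean, unit (population) variance.

    Constant columns carry no usable signal and would make the linear and
    quadratic kernel blocks degenerate, so they are dropped from the
    variable universe with a warning.  Idempotent: normalizing an already
    normalized table is the identity up to rounding.
    """
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples to normalize")
    mu = data.values.mean(axis=0)
    sd = data.values.std(axis=0)  # population sd, matching unit-variance columns
    keep = sd > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(data.names, keep) if not k]
        warnings.warn(
            f"dropping constant column(s) {dropped}: a constant is "
            "trivially ancestor-free and would poison the kernels",
            stacklevel=2,
        )
    names = tuple(n for n, k in zip(data.names, keep) if k)
    vals = (data.values[:, keep] - mu[keep]) / sd[keep]
    groups = {
        node: tuple(v for v in members if v in names)
        for node, members in data.groups.items()
    }
    groups = {node: members for node, members in groups.items() if members}
    return DataMatrix(vals, names, center=mu[keep], scale=sd[keep], groups=groups)
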