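"""Labeled directed dyadic matrices — the pipeline's universal currency.

A :class:`DyadicMatrix` is an n x n real matrix whose rows and columns are
individuals; cell (A, B) holds a directed dyadic quantity (minutes per hour,
events per hour, a 0/1 tie, or a similarity score).  The diagonal is
*undefined* and stored as NaN; no statistic in this package ever uses it.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, LabelMismatchError, SizeError

_BINARY_TOL = 0.0


class MatrixKind(str, enum.Enum):
    duration_rate = "duration_rate"  # minutes per hour, in [0, 60]
    event_rate = "event_rate"        # events per hour, >= 0
    binary = "binary"                # ties in {0, 1}
    similarity = "similarity"        # dyadic similarity (may be standardized)


def offdiag_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the n(n-1) off-diagonal cells, row-major order."""
    rows, cols = np.nonzero(~np.eye(n, dtype=bool))
    return rows, cols


@dataclass(frozen=True)
class DyadicMatrix:
    """Labeled n x n directed dyadic matrix with an undefined (NaN) diagonal.

    Parameters
    ----------
    labels : ordered individual ids (rows and columns share this order).
    values : square float array; the diagonal is forced to NaN on construction.
    directed : whether cell (A, B) may differ from (B, A).
    kind : what the values measure (see :class:`MatrixKind`).
    units : free-text unit string, e.g. ``"min/hr"`` or ``"events/hr"``.
    flagged : dyads whose value was set to 0 because the estimator's
        denominator was 0 (e.g. a dyad never observed in the same party).
    name : optional short name used in reports and error messages.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    directed: bool = True
    kind: MatrixKind = MatrixKind.event_rate
    units: str = ""
    flagged: frozenset[tuple[str, str]] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        if len(set(labels)) != len(labels):
            raise InputError("matrix labels must be unique")
        vals = np.array(self.values, dtype=float)
        n = len(labels)
        if vals.shape != (n, n):
            raise InputError(f"values shape {vals.shape} does not match {n} labels")
        np.fill_diagonal(vals, np.nan)
        vals.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", MatrixKind(self.kind))
        object.__setattr__(self, "flagged", frozenset(self.flagged))
        self._validate_range()

    def _validate_range(self) -> None:
        off = self.offdiag_values()
        if self.kind is MatrixKind.duration_rate:
            if off.size and (off.min() < -1e-9 or off.max() > 60 + 1e-9):
                raise InputError(
                    f"duration_rate values must lie in [0, 60] min/hr "
                    f"(got range [{off.min():.3g}, {off.max():.3g}])"
                )
        elif self.kind is MatrixKind.event_rate:
            if off.size and off.min() < -1e-9:
                raise InputError("event_rate values must be nonnegative")
        elif self.kind is MatrixKind.binary:
            if off.size and not np.isin(off, (0.0, 1.0)).all():
                raise InputError("binary matrix cells must be 0 or 1")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"unknown individual {label!r}") from None

    def loc(self, a: str, b: str) -> float:
        """Value of the directed cell (a, b)."""
        return float(self.values[self.index(a), self.index(b)])

    def offdiag_values(self) -> np.ndarray:
        """The n(n-1) off-diagonal cells in row-major, diagonal-skipped order."""
        rows, cols = offdiag_indices(self.n)
        return self.values[rows, cols]

    def is_symmetric(self, tol: float = 0.0) -> bool:
        v = np.nan_to_num(self.values)
        return bool(np.allclose(v, v.T, atol=tol, rtol=0.0))

    def with_values(self, values: np.ndarray, **changes) -> "DyadicMatrix":
        return replace(self, values=values, **changes)

    def relabelled(self, mapping: Mapping[str, str]) -> "DyadicMatrix":
        """Rename individuals without reordering (bijective mapping)."""
        new = tuple(mapping.get(l, l) for l in self.labels)
        flg = frozenset((mapping.get(a, a), mapping.get(b, b)) for a, b in self.flagged)
        return replace(self, labels=new, flagged=flg)

    def reordered(self, labels: Sequence[str]) -> "DyadicMatrix":
        """Same matrix with rows/columns listed in a new label order."""
        if set(labels) != set(self.labels):
            raise LabelMismatchError("reordering requires the same label set")
        idx = np.array([self.index(l) for l in labels])
        return replace(self, labels=tuple(labels), values=self.values[np.ix_(idx, idx)])

    # -- serialization ---------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        """Labeled square CSV; the undefined diagonal is written as NA."""
        self.to_dataframe().to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "DyadicMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        labels = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != labels:
            raise InputError(f"{path}: row and column labels differ")
        return cls(labels=labels, values=df.to_numpy(dtype=float), **kwargs)

    def to_edgelist(self, path: str | Path) -> None:
        """Tab-separated (source, target, weight) export for graph tools."""
        rows, cols = offdiag_indices(self.n)
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for r, c in zip(rows, cols):
                fh.write(f"{self.labels[r]}\t{self.labels[c]}\t{self.values[r, c]:.10g}\n")


def _require_shared_labels(matrices: Iterable[DyadicMatrix]) -> tuple[str, ...]:
    matrices = list(matrices)
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise LabelMismatchError(
                f"matrices {matrices[0].name or '<unnamed>'} and {m.name or '<unnamed>'} "
                "do not share the same ordered label set"
            )
    return labels


def dichotomize(matrix: DyadicMatrix) -> DyadicMatrix:
    """Binary presence/absence network: any value strictly over zero scores 1."""
    vals = np.where(matrix.values > _BINARY_TOL, 1.0, 0.0)
    return matrix.with_values(vals, kind=MatrixKind.binary, units="0/1",
                              name=f"{matrix.name}_present" if matrix.name else "")


def symmetrize_max(matrix: DyadicMatrix) -> DyadicMatrix:
    """Undirected tie present if either directed cell carries a 1."""
    if matrix.kind is not MatrixKind.binary:
        raise InputError("symmetrize_max requires a binary matrix (dichotomize first)")
    v = np.nan_to_num(matrix.values)
    vals = np.maximum(v, v.T)
    return matrix.with_values(vals, directed=False, kind=MatrixKind.binary)


def normalized_degree(matrix: DyadicMatrix, direction: str = "out") -> pd.Series:
    """Normalised degree centrality: the mean of a node's row (out) or column (in).

    For binary matrices this is the proportion of possible ties present
    (multiply by 100 to report a percentage).
    """
    if matrix.n < 2:
        raise SizeError("degree centrality needs at least 2 individuals")
    if direction not in ("out", "in"):
        raise InputError(f"direction must be 'out' or 'in', got {direction!r}")
    axis = 1 if direction == "out" else 0
    vals = np.nanmean(matrix.values, axis=axis)
    return pd.Series(vals, index=list(matrix.labels), name=f"{direction}_degree")
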