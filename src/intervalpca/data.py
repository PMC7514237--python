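"""Interval-valued data containers, derived matrices, I/O and synthesis.

An interval matrix holds, for each of ``n`` cases and ``m`` variables, a
closed interval ``[a_ij, b_ij]`` instead of a single number.  Such data arise
whenever a case aggregates a sequence of classical measurements (e.g. the
per-image facial distances of a surveillance sequence): the interval encodes
the internal variation of the case.

The module provides the containers (:class:`IntervalMatrix`,
:class:`RealizationMatrix`, :class:`VertexMatrix`, :class:`ColumnStats`),
the derived matrices used by interval PCA (center matrix, vertex matrix,
standardization with respect to a realization), CSV I/O in two dialects,
and a synthetic generator for tests and simulation studies.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "IntervalDataError",
    "IntervalMatrix",
    "RealizationMatrix",
    "VertexMatrix",
    "ColumnStats",
    "center_matrix",
    "vertex_matrix",
    "column_stats",
    "standardize_wrt",
    "read_interval_csv",
    "write_interval_csv",
    "synthesize_interval_matrix",
]


class IntervalDataError(ValueError):
    """Raised for invalid interval data (bounds, shapes, parsing)."""


def _as_2d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise IntervalDataError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class IntervalMatrix:
    """An n×m matrix of closed intervals ``[a_ij, b_ij]``.

    Parameters
    ----------
    lower, upper : (n, m) arrays
        Interval bounds; ``lower <= upper`` elementwise, all finite.
    case_labels : sequence of n strings, optional
        Row labels; defaults to ``c1..cn``.
    var_names : sequence of m strings, optional
        Column labels; defaults to ``X1..Xm``.
    """

    lower: np.ndarray
    upper: np.ndarray
    case_labels: tuple[str, ...] = field(default=())
    var_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        lower = _as_2d_float(self.lower, "lower")
        upper = _as_2d_float(self.upper, "upper")
        if lower.shape != upper.shape:
            raise IntervalDataError(
                f"bound shapes differ: {lower.shape} vs {upper.shape}"
            )
        n, m = lower.shape
        if n < 2 or m < 1:
            raise IntervalDataError(f"need n >= 2 cases and m >= 1 variables, got {n}×{m}")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise IntervalDataError("interval bounds must be finite")
        bad = lower > upper
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise IntervalDataError(
                f"lower bound exceeds upper at case {i}, variable {j}: "
                f"[{lower[i, j]}, {upper[i, j]}]"
            )
        labels = tuple(self.case_labels) or tuple(f"c{i + 1}" for i in range(n))
        names = tuple(self.var_names) or tuple(f"X{j + 1}" for j in range(m))
        if len(labels) != n:
            raise IntervalDataError(f"expected {n} case labels, got {len(labels)}")
        if len(names) != m:
            raise IntervalDataError(f"expected {m} variable names, got {len(names)}")
        lower.setflags(write=False)
        upper.setflags(write=False)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "case_labels", labels)
        object.__setattr__(self, "var_names", names)

    @property
    def n(self) -> int:
        return self.lower.shape[0]

    @property
    def m(self) -> int:
        return self.lower.shape[1]

    @property
    def width(self) -> np.ndarray:
        """Interval widths ``b - a`` (n×m)."""
        return self.upper - self.lower

    @property
    def nontrivial(self) -> np.ndarray:
        """Boolean n×m mask of nondegenerate intervals (``a < b``)."""
        return self.lower < self.upper

    def contains(self, values: np.ndarray, atol: float = 0.0) -> bool:
        """Whether a point matrix lies inside the interval hyper-rectangles."""
        v = np.asarray(values, dtype=float)
        return bool(
            (v >= self.lower - atol).all() and (v <= self.upper + atol).all()
        )

    def center(self) -> "RealizationMatrix":
        return center_matrix(self)

    def vertices(self) -> "VertexMatrix":
        return vertex_matrix(self)

    def realize(self, values: np.ndarray) -> "RealizationMatrix":
        """Wrap a point matrix as a realization of this interval matrix."""
        return RealizationMatrix(np.asarray(values, dtype=float), self)

    def to_dataframe(self) -> pd.DataFrame:
        """Bounds as a DataFrame with ``name.lo`` / ``name.hi`` columns."""
        data: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.var_names):
            data[f"{name}.lo"] = self.lower[:, j]
            data[f"{name}.hi"] = self.upper[:, j]
        return pd.DataFrame(data, index=list(self.case_labels))


@dataclass(frozen=True)
class RealizationMatrix:
    """A point matrix ``Z`` with ``a_ij <= Z_ij <= b_ij`` for its parent box."""

    values: np.ndarray
    parent: IntervalMatrix

    def __post_init__(self) -> None:
        values = _as_2d_float(self.values, "values")
        if values.shape != self.parent.lower.shape:
            raise IntervalDataError(
                f"realization shape {values.shape} does not match parent "
                f"{self.parent.lower.shape}"
            )
        if not self.parent.contains(values):
            raise IntervalDataError("realization leaves the interval hyper-rectangle")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class VertexMatrix:
    """Stacked hyper-rectangle corners of an interval matrix.

    Case ``i`` contributes ``2**m_i`` rows, where ``m_i`` counts its
    nondegenerate intervals; degenerate columns contribute their single
    value and are not duplicated.  Rows are ordered by binary counting over
    the nondegenerate columns (leftmost slowest, lower bound → 0).
    """

    rows: np.ndarray
    case_of_row: np.ndarray
    m_i: np.ndarray

    @property
    def N(self) -> int:
        return self.rows.shape[0]

    @property
    def m(self) -> int:
        return self.rows.shape[1]


def center_matrix(X: IntervalMatrix) -> RealizationMatrix:
    """Midpoint matrix ``(a + b) / 2``, the classical base of the center method."""
    return RealizationMatrix((X.lower + X.upper) / 2.0, X)


def vertex_matrix(X: IntervalMatrix) -> VertexMatrix:
    """Enumerate every corner of every case's hyper-rectangle.

    Returns the ``N×m`` stacked corner matrix with ``N = Σ_i 2**m_i`` and a
    row→case index map.
    """
    blocks: list[np.ndarray] = []
    case_idx: list[np.ndarray] = []
    m_i = X.nontrivial.sum(axis=1).astype(int)
    for i in range(X.n):
        cols = np.flatnonzero(X.nontrivial[i])
        k = cols.size
        block = np.tile(X.lower[i], (2**k, 1))
        if k:
            # binary counting: leftmost nontrivial column flips slowest
            bits = np.array(list(itertools.product((0, 1), repeat=k)))
            block[:, cols] = np.where(bits == 0, X.lower[i, cols], X.upper[i, cols])
        blocks.append(block)
        case_idx.append(np.full(2**k, i, dtype=int))
    return VertexMatrix(np.vstack(blocks), np.concatenate(case_idx), m_i)


@dataclass(frozen=True)
class ColumnStats:
    """Per-column mean and (population) standard deviation of a point matrix."""

    mean: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if (sd <= 0).any():
            j = int(np.flatnonzero(sd <= 0)[0])
            raise IntervalDataError(f"constant column {j}: zero standard deviation")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)


def column_stats(Z: RealizationMatrix | np.ndarray) -> ColumnStats:
    """Column means and population standard deviations (divisor ``n``)."""
    values = Z.values if isinstance(Z, RealizationMatrix) else np.asarray(Z, float)
    return ColumnStats(values.mean(axis=0), values.std(axis=0), values.shape[0])


def standardize_wrt(M, stats: ColumnStats):
    """Center and scale by ``sqrt(n)·sd`` with respect to reference stats.

    Entry ``(i, j)`` maps to ``(x - mean_j) / (sqrt(n)·sd_j)`` where ``n`` is
    the reference sample count.  Under this scaling the standardized
    reference matrix has columns with unit sum of squares, so its Gram
    matrix is the correlation matrix.  Interval input transforms both
    bounds (order is preserved since the scale is positive).
    """
    scale = np.sqrt(stats.n) * stats.sd
    if isinstance(M, IntervalMatrix):
        return IntervalMatrix(
            (M.lower - stats.mean) / scale,
            (M.upper - stats.mean) / scale,
            M.case_labels,
            M.var_names,
        )
    values = M.values if isinstance(M, RealizationMatrix) else np.asarray(M, float)
    return (values - stats.mean) / scale


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_BRACKET_RE = re.compile(r"^\s*\[\s*([^,\[\]]+?)\s*,\s*([^,\[\]]+?)\s*\]\s*$")

DIALECTS = ("bracket", "paired")


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise IntervalDataError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_interval_csv(path, dialect: str = "bracket") -> IntervalMatrix:
    """Read an interval matrix from CSV.

    Two dialects are supported: ``bracket`` stores each interval as a string
    cell ``"[a,b]"``; ``paired`` stores two float columns ``name.lo`` and
    ``name.hi`` per variable.  The first column holds the case label in both.
    """
    _check_dialect(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise IntervalDataError("interval CSV needs a case column plus data columns")
    labels = tuple(df.iloc[:, 0].astype(str))
    body = df.iloc[:, 1:]
    if dialect == "bracket":
        names = tuple(body.columns)
        n, m = body.shape
        lower = np.empty((n, m))
        upper = np.empty((n, m))
        for j, col in enumerate(body.columns):
            for i, cell in enumerate(body[col]):
                match = _BRACKET_RE.match(cell)
                if not match:
                    raise IntervalDataError(
                        f"malformed interval cell {cell!r} at row {i + 1}, column {col!r}"
                    )
                try:
                    a, b = float(match.group(1)), float(match.group(2))
                except ValueError as exc:
                    raise IntervalDataError(
                        f"non-numeric bound in cell {cell!r} at row {i + 1}, "
                        f"column {col!r}"
                    ) from exc
                if a > b:
                    raise IntervalDataError(
                        f"lower bound exceeds upper in cell {cell!r} at row {i + 1}, "
                        f"column {col!r}"
                    )
                lower[i, j], upper[i, j] = a, b
    else:
        cols = list(body.columns)
        if len(cols) % 2:
            raise IntervalDataError("paired dialect needs an even number of data columns")
        names_list = []
        for k in range(0, len(cols), 2):
            lo_col, hi_col = cols[k], cols[k + 1]
            if not (lo_col.endswith(".lo") and hi_col.endswith(".hi")):
                raise IntervalDataError(
                    f"expected '<name>.lo','<name>.hi' column pair, got "
                    f"{lo_col!r}, {hi_col!r}"
                )
            if lo_col[:-3] != hi_col[:-3]:
                raise IntervalDataError(
                    f"mismatched pair names: {lo_col!r} vs {hi_col!r}"
                )
            names_list.append(lo_col[:-3])
        names = tuple(names_list)
        try:
            values = body.astype(float).to_numpy()
        except ValueError as exc:
            raise IntervalDataError(f"non-numeric value in paired CSV: {exc}") from exc
        lower = values[:, 0::2]
        upper = values[:, 1::2]
        bad = lower > upper
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise IntervalDataError(
                f"lower bound exceeds upper at row {i + 1}, variable {names[j]!r}"
            )
    return IntervalMatrix(lower, upper, labels, names)


def write_interval_csv(X: IntervalMatrix, path, dialect: str = "bracket") -> None:
    """Write an interval matrix to CSV; lossless round-trip with the reader."""
    _check_dialect(dialect)
    if dialect == "bracket":
        cells = {
            name: [f"[{float(a)!r},{float(b)!r}]"
                   for a, b in zip(X.lower[:, j], X.upper[:, j])]
            for j, name in enumerate(X.var_names)
        }
        df = pd.DataFrame({"case": list(X.case_labels), **cells})
        df.to_csv(path, index=False)
    else:
        data: dict[str, list] = {"case": list(X.case_labels)}
        for j, name in enumerate(X.var_names):
            data[f"{name}.lo"] = [repr(float(v)) for v in X.lower[:, j]]
            data[f"{name}.hi"] = [repr(float(v)) for v in X.upper[:, j]]
        pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


def synthesize_interval_matrix(
    n: int = 27,
    m: int = 6,
    center_spec: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
    width_spec: Callable[[np.random.Generator, int, int], np.ndarray] | float | None = None,
    seed: int | None = None,
) -> IntervalMatrix:
    """Draw a random interval matrix with a planted low-rank center structure.

    The default center model emulates morphometric interval data: centers
    follow a correlated Gaussian driven by two latent factors (so a genuine
    two-component principal plane exists), and half-widths are independent
    folded Gaussians, giving asymmetric interval sizes across cases.

    Parameters
    ----------
    n, m : int
        Cases and variables.
    center_spec : callable(rng, n, m) -> (n, m) array, optional
        Generator for interval midpoints; default is the 2-factor model.
    width_spec : callable, scalar, or None
        Generator for half-widths (must be nonnegative); a scalar means a
        constant half-width; default draws ``|N(0, 1)|``.
    seed : int, optional
        Seeds the random stream; identical seeds give identical matrices.
    """
    rng = np.random.default_rng(seed)
    if center_spec is None:
        loadings = rng.normal(size=(m, 2))
        factors = rng.normal(size=(n, 2))
        centers = 100.0 + 10.0 * factors @ loadings.T + rng.normal(scale=2.0, size=(n, m))
    else:
        centers = np.asarray(center_spec(rng, n, m), dtype=float)
    if width_spec is None:
        half = np.abs(rng.normal(size=(n, m)))
    elif callable(width_spec):
        half = np.asarray(width_spec(rng, n, m), dtype=float)
    else:
        half = np.full((n, m), float(width_spec))
    if (half < 0).any():
        raise IntervalDataError("width_spec produced a negative half-width")
    return IntervalMatrix(centers - half, centers + half)
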