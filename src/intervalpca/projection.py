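"""Interval scores and dual interval loadings via sign-split closed forms.

Projecting every corner of a case's hyper-rectangle onto a principal axis
and taking the min/max is exponential in the number of nondegenerate
intervals.  Because a projection is linear, the extremes are attained at
the corner that pairs each negative loading with the opposite bound: the
lower score uses ``b`` on negative-loading columns and ``a`` elsewhere, and
the upper score swaps the roles.  The same argument on the case-side
(dual) eigenvectors bounds each variable's correlation-circle coordinate
over all realizations of the box.

A brute-force corner-enumeration implementation is included as an
independent oracle for the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IntervalMatrix, RealizationMatrix, standardize_wrt, vertex_matrix
from .pca import DualModel, PCAModel, project_supplementary

__all__ = [
    "IntervalScores",
    "IntervalLoadings",
    "interval_scores",
    "interval_scores_bruteforce",
    "dual_interval_loadings",
]


@dataclass(frozen=True)
class IntervalScores:
    """Per-case, per-component score intervals ``[lo_ik, hi_ik]``."""

    lo: np.ndarray
    hi: np.ndarray
    case_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.lo > self.hi + 1e-12).any():
            raise ValueError("interval score lower bound exceeds upper bound")

    @property
    def n_components(self) -> int:
        return self.lo.shape[1]


@dataclass(frozen=True)
class IntervalLoadings:
    """Bounds on variable-on-component coordinates over all realizations."""

    lo: np.ndarray
    hi: np.ndarray
    var_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.lo > self.hi + 1e-12).any():
            raise ValueError("interval loading lower bound exceeds upper bound")


def _split(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # zero loadings count as nonnegative; the bound is unchanged either way
    pos = np.where(W >= 0, W, 0.0)
    neg = np.where(W < 0, W, 0.0)
    return pos, neg


def _score_bounds(X: IntervalMatrix, model: PCAModel, s: int):
    scale = model.stats.sd          # (x - mean)/σ: the reported score scale
    a = (X.lower - model.stats.mean) / scale
    b = (X.upper - model.stats.mean) / scale
    pos, neg = _split(model.eigvecs[:, :s])
    return a @ pos + b @ neg, b @ pos + a @ neg


def interval_scores(X: IntervalMatrix, model: PCAModel,
                    n_components: int | None = None) -> IntervalScores:
    """Score intervals by the sign-split closed form.

    The interval bounds are standardized with respect to the fitted
    matrix's stats, then combined per the loading signs; the result equals
    the min/max over all ``2**m_i`` corner projections exactly.
    """
    if X.m != model.m:
        raise ValueError(f"interval matrix has {X.m} variables, model expects {model.m}")
    s = model.n_components if n_components is None else int(n_components)
    lo, hi = _score_bounds(X, model, s)
    return IntervalScores(lo, hi, X.case_labels)


def interval_scores_bruteforce(X: IntervalMatrix, model: PCAModel,
                               n_components: int | None = None,
                               guard: int = 10**6) -> IntervalScores:
    """Oracle: min/max over explicitly enumerated corner projections.

    Refuses to enumerate more than ``guard`` vertex rows.
    """
    s = model.n_components if n_components is None else int(n_components)
    V = vertex_matrix(X)
    if V.N > guard:
        raise ValueError(f"vertex enumeration of {V.N} rows exceeds guard {guard}")
    std_rows = (V.rows - model.stats.mean) / model.stats.sd
    proj = project_supplementary(std_rows, model)[:, :s]
    lo = np.empty((X.n, s))
    hi = np.empty((X.n, s))
    for i in range(X.n):
        block = proj[V.case_of_row == i]
        lo[i] = block.min(axis=0)
        hi[i] = block.max(axis=0)
    return IntervalScores(lo, hi, X.case_labels)


def dual_interval_loadings(X: IntervalMatrix, Z: RealizationMatrix,
                           dual: DualModel) -> IntervalLoadings:
    """Bounds on each variable's dual coordinate over all Z′ ∈ the box.

    The interval bounds are standardized with respect to Z on the
    ``sqrt(n)·σ`` scale (the scale on which the dual directions live); for
    each variable i and dual direction j, cases with negative v_kj
    contribute their upper bound to the lower coordinate and vice versa.
    The realized coordinate ``r_ij`` of any Z′ in the box lies inside.
    """
    from .data import column_stats

    stats = column_stats(Z)
    std = standardize_wrt(X, stats)
    V = dual.dual_eigvecs
    pos, neg = _split(V)
    lo = std.lower.T @ pos + std.upper.T @ neg
    hi = std.upper.T @ pos + std.lower.T @ neg
    return IntervalLoadings(lo, hi, X.var_names)
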