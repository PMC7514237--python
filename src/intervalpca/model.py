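"""Model/Results interface for interval-valued PCA.

:class:`IntervalPCA` is the model object: an interval matrix plus a choice
of method — ``center`` (classical PCA on interval midpoints), ``vertex``
(PCA on the stacked hyper-rectangle corners), ``bp-distance`` and
``bp-variance`` (PCA at the Best Point matrix optimized inside the box for
the φ or Λ criterion).  ``fit()`` returns an :class:`IntervalPCAResults`
carrying the eigenstructure, the per-case score intervals, the retained
variance, the vertex distance φ and the variable–component correlations,
with a ``summary()`` table and a principal-plane plot.

Free functions assemble method-comparison tables (variance, distance,
correlation) from several fitted results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    IntervalMatrix,
    RealizationMatrix,
    column_stats,
    read_interval_csv,
    standardize_wrt,
    vertex_matrix,
)
from .objectives import phi
from .optimize import BestPointResult, OptimizerConfig, optimize_distance, optimize_variance
from .pca import DualModel, PCAModel, dual_components, fit_pca
from .projection import IntervalScores, interval_scores

__all__ = [
    "METHODS",
    "IntervalPCA",
    "IntervalPCAResults",
    "compare",
    "variance_table",
    "distance_table",
    "correlation_table",
    "plot_principal_plane",
]

METHODS = ("center", "vertex", "bp-distance", "bp-variance")

_DISPLAY = {
    "center": "Center",
    "vertex": "Vertex",
    "bp-distance": "Best Point Distance",
    "bp-variance": "Best Point Variance",
}


def _anchor_signs(pca: PCAModel, vertex_rows: np.ndarray,
                  var_names: Sequence[str],
                  anchors: Sequence[str | None]) -> PCAModel:
    """Re-sign components so each anchor variable correlates positively.

    The correlation is taken between the anchor's vertex-matrix column and
    the vertex rows' supplementary scores on that component; a zero
    correlation leaves the sign untouched.
    """
    W = pca.eigvecs.copy()
    scores = pca.scores.copy()
    std = (vertex_rows - pca.stats.mean) / pca.stats.sd
    proj = std @ W
    for k, anchor in enumerate(anchors):
        if anchor is None:
            continue
        if anchor not in var_names:
            raise ValueError(f"anchor variable {anchor!r} not among {tuple(var_names)}")
        j = list(var_names).index(anchor)
        r = np.corrcoef(vertex_rows[:, j], proj[:, k])[0, 1]
        if r < 0:
            W[:, k] = -W[:, k]
            scores[:, k] = -scores[:, k]
    return dataclasses.replace(pca, eigvecs=W, scores=scores)


class IntervalPCA:
    """Interval-valued principal component model.

    Parameters
    ----------
    X : IntervalMatrix
        The interval data.
    method : {"center", "vertex", "bp-distance", "bp-variance"}
        Which base matrix the PCA is fitted on.
    n_components : int
        Retained components s (used by the Best Point objectives and by
        the reported score intervals); defaults to the principal plane,
        s = 2.
    sign_anchors : sequence of variable names or None entries, optional
        Per-component sign anchors: each listed component is re-signed so
        that the anchor variable's correlation with it is positive.
        Default keeps the largest-|loading|-positive convention.
    optimizer : OptimizerConfig, optional
        Settings for the Best Point search (ignored by center/vertex).
    """

    def __init__(self, X: IntervalMatrix, method: str = "center",
                 n_components: int = 2,
                 sign_anchors: Sequence[str | None] | None = None,
                 optimizer: OptimizerConfig | None = None) -> None:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        if not 1 <= n_components <= X.m:
            raise ValueError(f"n_components must be in [1, {X.m}]")
        self.X = X
        self.method = method
        self.n_components = int(n_components)
        self.sign_anchors = tuple(sign_anchors) if sign_anchors else ()
        self.optimizer = optimizer or OptimizerConfig()

    @classmethod
    def from_csv(cls, path, dialect: str = "bracket", **kwargs) -> "IntervalPCA":
        return cls(read_interval_csv(path, dialect), **kwargs)

    @classmethod
    def from_arrays(cls, lower, upper, case_labels=(), var_names=(), **kwargs) -> "IntervalPCA":
        return cls(IntervalMatrix(lower, upper, case_labels, var_names), **kwargs)

    def fit(self) -> "IntervalPCAResults":
        X, s = self.X, self.n_components
        vertices = vertex_matrix(X)
        best_point: BestPointResult | None = None
        if self.method == "center":
            fitted = X.center()
            pca = fit_pca(fitted, s)
            fitted_values = fitted.values
        elif self.method == "vertex":
            pca = fit_pca(vertices.rows, s)
            fitted_values = vertices.rows
        else:
            opt = optimize_distance if self.method == "bp-distance" else optimize_variance
            best_point = opt(X, s, self.optimizer)
            fitted = best_point.Z_opt
            pca = fit_pca(fitted, s)
            fitted_values = fitted.values
        if self.sign_anchors:
            pca = _anchor_signs(pca, vertices.rows, X.var_names, self.sign_anchors)

        scores = interval_scores(X, pca, s)
        std_vertices = (vertices.rows - pca.stats.mean) / pca.stats.sd
        vertex_scores = std_vertices @ pca.eigvecs[:, :s]
        correlations = pd.DataFrame(
            [
                [np.corrcoef(vertices.rows[:, j], vertex_scores[:, k])[0, 1]
                 for k in range(s)]
                for j in range(X.m)
            ],
            index=list(X.var_names),
            columns=[f"PC{k + 1}" for k in range(s)],
        )
        if self.method == "vertex":
            # distance of the corners to the vertex-PCA axes, measured on
            # the center-matrix standardization
            center_stats = column_stats(X.center())
            tilde = standardize_wrt(vertices.rows, center_stats)
            Ws = pca.eigvecs[:, :s]
            resid = tilde - (tilde @ Ws) @ Ws.T
            phi_value = float(np.sum(resid * resid))
        else:
            phi_value = phi(X, X.realize(fitted_values), s).value
        return IntervalPCAResults(
            model=self,
            method=self.method,
            pca=pca,
            fitted_values=fitted_values,
            scores=scores,
            correlations=correlations,
            phi_value=phi_value,
            best_point=best_point,
        )


@dataclass
class IntervalPCAResults:
    """Fitted interval PCA: estimates, intervals and diagnostics."""

    model: IntervalPCA
    method: str
    pca: PCAModel
    fitted_values: np.ndarray
    scores: IntervalScores
    correlations: pd.DataFrame
    phi_value: float
    best_point: BestPointResult | None = None

    @property
    def X(self) -> IntervalMatrix:
        return self.model.X

    @property
    def n_components(self) -> int:
        return self.model.n_components

    @property
    def eigvals(self) -> np.ndarray:
        return self.pca.eigvals

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio

    @property
    def cumulative_percent(self) -> np.ndarray:
        """Cumulative percent variance per component (ends at 100)."""
        return 100.0 * np.cumsum(self.explained_variance_ratio)

    def dual(self, n_components: int | None = None) -> DualModel:
        """Case-side dual eigenvectors of the fitted matrix."""
        return dual_components(self.pca, self.fitted_values, n_components)

    def scores_frame(self) -> pd.DataFrame:
        """Interval scores as a DataFrame of [lo, hi] string cells."""
        s = self.scores
        return pd.DataFrame(
            {
                f"PC{k + 1}": [f"[{lo:.2f},{hi:.2f}]" for lo, hi in
                               zip(s.lo[:, k], s.hi[:, k])]
                for k in range(s.n_components)
            },
            index=list(s.case_labels),
        )

    def summary(self) -> str:
        lines = [
            "Interval PCA results",
            "=" * 58,
            f"Method:            {_DISPLAY[self.method]}",
            f"Cases / variables: {self.X.n} / {self.X.m}",
            f"Components (s):    {self.n_components}",
            f"Vertex rows:       {vertex_matrix(self.X).N}",
            f"phi (vertex dist): {self.phi_value:.4f}",
        ]
        if self.best_point is not None:
            bp = self.best_point
            lines.append(
                f"Best Point search: {bp.criterion}, {bp.n_iter} iterations, "
                f"converged={bp.converged}, start={bp.start_index}"
            )
        lines.append("-" * 58)
        lines.append(f"{'component':<12}{'eigenvalue':>12}{'% var':>10}{'cum %':>10}")
        cum = self.cumulative_percent
        for k, lam in enumerate(self.eigvals):
            lines.append(
                f"{'PC' + str(k + 1):<12}{lam:>12.4f}"
                f"{100 * self.explained_variance_ratio[k]:>10.2f}{cum[k]:>10.2f}"
            )
        lines.append("-" * 58)
        lines.append("Correlation of variables with retained components:")
        lines.append(self.correlations.round(2).to_string())
        return "\n".join(lines)

    def plot_principal_plane(self, components: tuple[int, int] = (1, 2),
                             path=None, ax=None):
        return plot_principal_plane(self, components=components, path=path, ax=ax)


def compare(X: IntervalMatrix, methods: Sequence[str] = METHODS,
            n_components: int = 2,
            sign_anchors: Sequence[str | None] | None = None,
            optimizer: OptimizerConfig | None = None) -> dict[str, IntervalPCAResults]:
    """Fit several methods on the same interval matrix."""
    return {
        method: IntervalPCA(X, method=method, n_components=n_components,
                            sign_anchors=sign_anchors, optimizer=optimizer).fit()
        for method in methods
    }


def variance_table(results: dict[str, IntervalPCAResults]) -> pd.DataFrame:
    """Cumulative percent variance per component, one column per method."""
    table = pd.DataFrame(
        {_DISPLAY[name]: res.cumulative_percent for name, res in results.items()},
        index=[f"PC{k + 1}" for k in range(next(iter(results.values())).X.m)],
    )
    return table


def distance_table(results: dict[str, IntervalPCAResults]) -> pd.Series:
    """Vertex distance φ of each method's fitted matrix."""
    return pd.Series({_DISPLAY[name]: res.phi_value for name, res in results.items()},
                     name="phi")


def correlation_table(results: dict[str, IntervalPCAResults],
                      component: int = 1) -> pd.DataFrame:
    """Correlation of each variable with one component, per method.

    The correlation is computed between the vertex-matrix column of the
    variable and the vertex rows' supplementary scores on the method's
    component, so all methods are judged on the same underlying points.
    """
    rows = {}
    for name, res in results.items():
        rows[f"{_DISPLAY[name]}-PC{component}"] = res.correlations[f"PC{component}"]
    return pd.DataFrame(rows).T


def plot_principal_plane(result: IntervalPCAResults,
                         components: tuple[int, int] = (1, 2),
                         path=None, ax=None):
    """Draw each case as an axis-aligned rectangle on two components."""
    import matplotlib
    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    i, j = components[0] - 1, components[1] - 1
    s = result.scores
    if max(i, j) >= s.n_components:
        raise ValueError("requested components exceed the retained count")
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 8))
    else:
        fig = ax.figure
    for label, xlo, xhi, ylo, yhi in zip(
        s.case_labels, s.lo[:, i], s.hi[:, i], s.lo[:, j], s.hi[:, j]
    ):
        ax.add_patch(Rectangle((xlo, ylo), xhi - xlo, yhi - ylo,
                               fill=False, edgecolor="tab:blue", linewidth=0.8))
        ax.annotate(label, ((xlo + xhi) / 2, (ylo + yhi) / 2),
                    ha="center", va="center", fontsize=7)
    ax.set_xlim(s.lo[:, i].min() - 0.5, s.hi[:, i].max() + 0.5)
    ax.set_ylim(s.lo[:, j].min() - 0.5, s.hi[:, j].max() + 0.5)
    ax.axhline(0.0, color="grey", linewidth=0.5)
    ax.axvline(0.0, color="grey", linewidth=0.5)
    ax.set_xlabel(f"PC{components[0]}")
    ax.set_ylabel(f"PC{components[1]}")
    ax.set_title(f"{_DISPLAY[result.method]} principal plane")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
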