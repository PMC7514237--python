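"""Best Point objective functions: φ (vertex distance) and Λ (inertia).

φ(Z, s) measures how far the hyper-rectangle corners fall from the rank-s
principal subspace of Z: the vertex matrix is standardized with respect to
Z, projected onto span{w_1..w_s}, and the squared residual norms are
summed.  Λ(Z, s) is the inertia retained by the first s components, i.e.
the sum of the top-s correlation-matrix eigenvalues of Z.  The Best Point
methods pick Z inside the interval box to minimize φ or maximize Λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IntervalMatrix, RealizationMatrix, standardize_wrt, vertex_matrix
from .pca import fit_pca

__all__ = ["ObjectiveValue", "phi", "lambda_sum"]


@dataclass(frozen=True)
class ObjectiveValue:
    """An objective evaluation: the value, the component count s and the Z."""

    value: float
    s: int
    Z: RealizationMatrix | np.ndarray


def _check_s(s: int, m: int) -> int:
    s = int(s)
    if not 1 <= s <= m:
        raise ValueError(f"s must be in [1, {m}], got {s}")
    return s


def phi(X: IntervalMatrix, Z: RealizationMatrix, s: int = 2,
        vertex_rows: np.ndarray | None = None) -> ObjectiveValue:
    """Summed squared distance from standardized vertices to Z's subspace.

    Fits correlation PCA on Z, standardizes the full vertex matrix of X
    with respect to Z (``sqrt(n)·σ`` scale), and returns
    ``Σ_i ‖x̃_i − W_s W_sᵗ x̃_i‖²``.  Equals ``Σ‖x̃‖² − Σ‖W_sᵗx̃‖²``
    algebraically (orthonormal columns); the residual form is computed
    directly.  ``vertex_rows`` lets a caller evaluating many Z reuse one
    corner enumeration.
    """
    if Z.parent is not X and not X.contains(Z.values):
        raise ValueError("Z does not belong to the interval matrix X")
    s = _check_s(s, X.m)
    model = fit_pca(Z)
    Ws = model.eigvecs[:, :s]
    if vertex_rows is None:
        vertex_rows = vertex_matrix(X).rows
    tilde = standardize_wrt(vertex_rows, model.stats)
    resid = tilde - (tilde @ Ws) @ Ws.T
    return ObjectiveValue(float(np.sum(resid * resid)), s, Z)


def lambda_sum(Z: RealizationMatrix | np.ndarray, s: int = 2) -> ObjectiveValue:
    """Retained inertia: sum of the top-s correlation eigenvalues of Z."""
    m = Z.m if isinstance(Z, RealizationMatrix) else np.asarray(Z).shape[1]
    s = _check_s(s, m)
    model = fit_pca(Z)
    return ObjectiveValue(float(model.eigvals[:s].sum()), s, Z)
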