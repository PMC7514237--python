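"""Classical correlation PCA with fixed conventions, plus the row/column dual.

Only correlation PCA (standardized variables) is supported: every
standardization in the interval machinery divides by the column standard
deviation, so a covariance mode would be inconsistent with the rest of the
package.

Scale conventions.  Internally the fitted matrix is standardized as
``Z̃ = (Z − mean) / (sqrt(n)·σ)`` so that ``Z̃ᵗZ̃`` is the correlation matrix
and the case-side Gram matrix ``Z̃Z̃ᵗ`` shares its nonzero eigenvalues
(duality).  Reported scores use the conventional ``(Z − mean)/σ`` scale
(``sqrt(n)`` times the internal one), under which the k-th score column has
population variance λ_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ColumnStats, RealizationMatrix, column_stats, standardize_wrt

__all__ = ["PCAModel", "DualModel", "fit_pca", "project_supplementary",
           "dual_components", "dual_scores"]


@dataclass(frozen=True)
class PCAModel:
    """Fitted correlation PCA of a point matrix.

    Attributes
    ----------
    stats : ColumnStats
        Mean/sd of the fitted matrix; supplementary points must be
        standardized with respect to these.
    eigvals : (m,) array
        Eigenvalues of the correlation matrix, non-increasing; they sum to m.
    eigvecs : (m, m) array
        Orthonormal eigenvector columns ``w_1..w_m`` (the basis β(Z)).  Each
        is signed so its largest-|entry| loading is positive.
    scores : (n, m) array
        Case scores on the ``(x − mean)/σ`` scale.
    n_components : int
        Retained component count s (metadata; all m components are stored).
    """

    stats: ColumnStats
    eigvals: np.ndarray
    eigvecs: np.ndarray
    scores: np.ndarray
    n_components: int

    @property
    def m(self) -> int:
        return self.eigvecs.shape[0]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigvals / self.eigvals.sum()


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| loading is positive.

    ``argmax`` returns the first maximal index, so ties resolve to the
    lower variable index, making the convention deterministic.
    """
    anchors = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[anchors, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def fit_pca(Z: RealizationMatrix | np.ndarray, n_components: int | None = None) -> PCAModel:
    """Eigendecompose the correlation matrix of a point matrix.

    Raises on constant columns (zero standard deviation) and on
    ``n_components > m``.
    """
    values = Z.values if isinstance(Z, RealizationMatrix) else np.asarray(Z, float)
    stats = column_stats(values)
    m = values.shape[1]
    s = m if n_components is None else int(n_components)
    if not 1 <= s <= m:
        raise ValueError(f"n_components must be in [1, {m}], got {s}")
    Zt = standardize_wrt(values, stats)
    corr = Zt.T @ Zt
    eigvals, W = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]          # descending; eigh is ascending
    eigvals = np.maximum(eigvals[order], 0.0)
    W = _fix_signs(W[:, order])
    scores = np.sqrt(stats.n) * Zt @ W
    return PCAModel(stats, eigvals, W, scores, s)


def project_supplementary(points: np.ndarray, model: PCAModel) -> np.ndarray:
    """Project already-standardized supplementary rows onto the basis.

    ``points`` must be standardized with respect to ``model.stats`` (any
    consistent positive scale); returns coordinates on all m components.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != model.m:
        raise ValueError(
            f"points have {pts.shape[-1]} columns, model expects {model.m}"
        )
    return pts @ model.eigvecs


@dataclass(frozen=True)
class DualModel:
    """Case-side eigenvectors of ``Z̃Z̃ᵗ`` and the dual identities.

    ``dual_eigvecs`` holds v_1..v_s (n×s, orthonormal); ``primal_from_dual``
    holds u_ℓ = Z̃ᵗ v_ℓ / sqrt(λ_ℓ), which coincide (up to sign convention)
    with the correlation-matrix eigenvectors.  Conversely
    v_ℓ = Z̃ u_ℓ / sqrt(λ_ℓ).
    """

    eigvals: np.ndarray
    dual_eigvecs: np.ndarray
    primal_from_dual: np.ndarray


def dual_components(model: PCAModel, Z: RealizationMatrix | np.ndarray,
                    n_components: int | None = None,
                    zero_tol: float = 1e-10) -> DualModel:
    """Dual (case-side) eigenvectors via v_ℓ = Z̃ u_ℓ / sqrt(λ_ℓ).

    Only directions with λ_ℓ > 0 admit a dual vector; requesting more
    raises.
    """
    values = Z.values if isinstance(Z, RealizationMatrix) else np.asarray(Z, float)
    Zt = standardize_wrt(values, model.stats)
    s = model.n_components if n_components is None else int(n_components)
    lam = model.eigvals[:s]
    if (lam <= zero_tol).any():
        bad = int(np.flatnonzero(lam <= zero_tol)[0])
        raise ValueError(
            f"component {bad + 1} has (numerically) zero eigenvalue; "
            "no dual eigenvector exists"
        )
    U = model.eigvecs[:, :s]
    V = Zt @ U / np.sqrt(lam)
    return DualModel(lam.copy(), V, Zt.T @ V / np.sqrt(lam))


def dual_scores(Zt: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Variable coordinates r_ij = Σ_k Z̃_ki v_kj along the dual directions.

    With the ``sqrt(n)·σ`` standardization these are the correlation-circle
    coordinates: r_ij is the Pearson correlation of variable i with
    component j.
    """
    return np.asarray(Zt, float).T @ np.asarray(V, float)
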