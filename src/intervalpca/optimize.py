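"""Box-constrained search for the Best Point matrix inside an interval box.

The decision variable is the whole realization matrix Z, reparameterized
entrywise as ``Z = a + t∘(b − a)`` with ``t ∈ [0, 1]^{n·m}`` so the bounds
are uniform and scale-free.  Degenerate entries (a = b) are fixed and
excluded from the search.  Optimization starts at the center matrix
(t = 1/2), optionally adding seeded random corner starts.

Both criteria — minimizing the vertex distance φ and maximizing the
retained inertia Λ — are continuous but only piecewise smooth (eigenvalue
crossings), so the default solver is a projected quasi-Newton method
(L-BFGS-B) fed central finite-difference gradients, with a cyclic
coordinate-descent / golden-section fallback that uses no gradients at
all.  The returned matrix is never worse than the best point evaluated,
so the criterion value at the result always improves on (or equals) the
center start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .data import IntervalDataError, IntervalMatrix, RealizationMatrix
from .objectives import lambda_sum, phi

__all__ = ["OptimizerConfig", "BestPointResult", "optimize_distance", "optimize_variance"]

logger = logging.getLogger(__name__)

_PENALTY = 1e12          # returned for iterates with a constant column
_FD_STEP = 1e-6          # central-difference step in t-space


@dataclass(frozen=True)
class OptimizerConfig:
    """Search settings.

    ``tol`` is the absolute objective-change tolerance between iterations;
    ``max_iter`` caps iterations (sweeps, for coordinate descent);
    ``n_starts`` adds seeded random corner starts beyond the mandatory
    center start; ``method`` selects the solver.
    """

    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 20191019
    n_starts: int = 1
    method: str = "projected-quasi-newton"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("max_iter and n_starts must be >= 1")
        if self.method not in ("projected-quasi-newton", "coordinate-descent"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class BestPointResult:
    """Outcome of a Best Point search.

    ``objective_trace`` is on the criterion scale (φ decreasing, Λ
    increasing); ``Z_opt`` always lies in the box and its criterion value
    is at least as good as at the center matrix.
    """

    Z_opt: RealizationMatrix
    objective_trace: np.ndarray
    converged: bool
    criterion: str
    n_iter: int
    start_index: int = 0
    objective_value: float = field(default=float("nan"))


class _Tracker:
    """Wraps the internal (minimized) objective; remembers the best point."""

    def __init__(self, fun):
        self.fun = fun
        self.best_value = np.inf
        self.best_t: np.ndarray | None = None
        self.n_eval = 0

    def __call__(self, t: np.ndarray) -> float:
        self.n_eval += 1
        try:
            value = self.fun(t)
        except IntervalDataError:
            return _PENALTY
        if value < self.best_value:
            self.best_value = value
            self.best_t = t.copy()
        return value


def _central_gradient(fun, t: np.ndarray, h: float = _FD_STEP) -> np.ndarray:
    grad = np.empty_like(t)
    for i in range(t.size):
        tp = t.copy()
        tm = t.copy()
        tp[i] = min(tp[i] + h, 1.0)
        tm[i] = max(tm[i] - h, 0.0)
        denom = tp[i] - tm[i]
        grad[i] = (fun(tp) - fun(tm)) / denom if denom > 0 else 0.0
    return grad


def _quasi_newton(tracker: _Tracker, t0: np.ndarray, cfg: OptimizerConfig):
    trace = [tracker(t0)]
    converged = False

    def callback(tk):
        value = tracker(tk)
        logger.debug("iteration %d: objective %.10g", len(trace), value)
        prev = trace[-1]
        trace.append(value)
        if abs(prev - value) < cfg.tol:
            raise StopIteration

    try:
        minimize(
            tracker,
            t0,
            jac=lambda t: _central_gradient(tracker, t),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * t0.size,
            callback=callback,
            options={"maxiter": cfg.max_iter, "ftol": 1e-16, "gtol": 1e-12},
        )
        # scipy may stop on its own criteria; treat a sub-tol final step as converged
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < cfg.tol:
            converged = True
    except StopIteration:
        converged = True
    return np.asarray(trace), converged


def _coordinate_descent(tracker: _Tracker, t0: np.ndarray, cfg: OptimizerConfig):
    t = t0.copy()
    trace = [tracker(t)]
    converged = False
    for sweep in range(cfg.max_iter):
        for i in range(t.size):
            def line(ti, i=i):
                u = t.copy()
                u[i] = ti
                return tracker(u)

            res = minimize_scalar(line, bounds=(0.0, 1.0), method="bounded",
                                  options={"xatol": 1e-8})
            t[i] = float(np.clip(res.x, 0.0, 1.0))
        value = tracker(t)
        logger.debug("sweep %d: objective %.10g", sweep + 1, value)
        prev = trace[-1]
        trace.append(value)
        if abs(prev - value) < cfg.tol:
            converged = True
            break
    return np.asarray(trace), converged


def _optimize(X: IntervalMatrix, objective, criterion: str, sign: float,
              cfg: OptimizerConfig) -> BestPointResult:
    lower = X.lower.ravel()
    span = (X.upper - X.lower).ravel()
    free = span > 0

    def to_Z(t: np.ndarray) -> RealizationMatrix:
        full = lower + np.clip(t, 0.0, 1.0) * span
        return RealizationMatrix(
            np.clip(full, lower, X.upper.ravel()).reshape(X.lower.shape), X
        )

    def internal(t_free: np.ndarray) -> float:
        t = np.full(lower.size, 0.5)
        t[free] = t_free
        return sign * objective(to_Z(t))

    d = int(free.sum())
    if d == 0:
        # the box is a single point: nothing to optimize
        Z = X.center()
        value = objective(Z)
        return BestPointResult(Z, np.asarray([value]), True, criterion, 0,
                               objective_value=value)

    rng = np.random.default_rng(cfg.seed)
    starts = [np.full(d, 0.5)]
    for _ in range(cfg.n_starts - 1):
        starts.append(rng.integers(0, 2, size=d).astype(float))

    runs = []
    for k, t0 in enumerate(starts):
        tracker = _Tracker(internal)
        if cfg.method == "projected-quasi-newton":
            trace, converged = _quasi_newton(tracker, t0, cfg)
        else:
            trace, converged = _coordinate_descent(tracker, t0, cfg)
        runs.append((tracker.best_value, k, tracker.best_t, trace, converged))
        logger.info("start %d (%s): best %s = %.10g after %d evaluations",
                    k, cfg.method, criterion, sign * tracker.best_value,
                    tracker.n_eval)

    best_value, k, best_t, trace, converged = min(runs, key=lambda r: (r[0], r[1]))
    t = np.full(lower.size, 0.5)
    t[free] = best_t
    return BestPointResult(
        Z_opt=to_Z(t),
        objective_trace=sign * trace,
        converged=converged,
        criterion=criterion,
        n_iter=len(trace) - 1,
        start_index=k,
        objective_value=sign * best_value,
    )


def optimize_distance(X: IntervalMatrix, s: int = 2,
                      cfg: OptimizerConfig | None = None) -> BestPointResult:
    """Find Z_φ minimizing the vertex distance φ(Z, s) over the box."""
    cfg = cfg or OptimizerConfig()
    from .data import vertex_matrix

    rows = vertex_matrix(X).rows        # enumerate the corners once
    return _optimize(X, lambda Z: phi(X, Z, s, vertex_rows=rows).value,
                     "distance", 1.0, cfg)


def optimize_variance(X: IntervalMatrix, s: int = 2,
                      cfg: OptimizerConfig | None = None) -> BestPointResult:
    """Find Z_Λ maximizing the retained inertia Λ(Z, s) over the box."""
    cfg = cfg or OptimizerConfig()
    return _optimize(X, lambda Z: lambda_sum(Z, s).value, "variance", -1.0, cfg)
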