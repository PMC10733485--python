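"""L2,1-regularized multi-view least squares solved by FISTA.

Each view v contributes a least-squares term on its own weight column
u_v against the shared +/-1 label vector; the L2,1 penalty (sum of row
L2 norms of the stacked weight matrix U) couples the views, zeroing
whole feature rows and thereby selecting CSP features jointly across
views:

    U* = argmin_U  1/2 sum_v ||V_v u_v - y||^2  +  lambda ||U||_{2,1}

The smooth term is block-diagonal across views, so the gradient step
decouples per column while the proximal step (row-wise soft shrinkage)
couples them. The regularization strength is parameterized as a fraction
``lam`` of ``lambda_max``, the smallest penalty for which U = 0 is
optimal; lam = 1 therefore always returns the all-zero solution and the
grid {0, 0.1, ..., 1} is scale-free.

Accelerated proximal gradient (FISTA) with a fixed 1/L step and a
function-value restart gives a monotone objective trace; L is the
largest Gram eigenvalue over views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csp import ViewFeatures

__all__ = ["MultiViewWeights", "lambda_max", "l21_prox", "l21_solve", "l21_objective"]

ZERO_ROW_RTOL = 1e-8  # row-norm <= rtol * max row norm counts as zero


@dataclass(frozen=True)
class MultiViewWeights:
    """Solution of the multi-view problem: rows = features, columns = views."""

    U: np.ndarray
    lam: float
    lambda_max: float
    objective_trace: np.ndarray
    converged: bool

    def nonzero_rows(self) -> np.ndarray:
        """Indices of rows with non-negligible L2 norm."""
        norms = np.linalg.norm(self.U, axis=1)
        if norms.max() == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(norms > ZERO_ROW_RTOL * norms.max())


def _stack(views: list[ViewFeatures]) -> tuple[list[np.ndarray], np.ndarray]:
    if not views:
        raise ValueError("no views given")
    y = views[0].y
    for v in views[1:]:
        if not np.array_equal(v.y, y):
            raise ValueError("all views must share the same label vector")
    return [v.X for v in views], y


def lambda_max(views: list[ViewFeatures]) -> float:
    """Smallest penalty for which U = 0 solves the problem.

    Equals the largest row L2 norm, across views, of the gradient of the
    smooth term at U = 0 (i.e. of the matrix with entries (V_v^T y)_i).
    """
    Xs, y = _stack(views)
    G = np.column_stack([X.T @ y for X in Xs])
    return float(np.linalg.norm(G, axis=1).max())


def l21_prox(U: np.ndarray, threshold: float) -> np.ndarray:
    """Row-wise group soft-threshold: u_i <- max(0, 1 - t/||u_i||) u_i."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - threshold / norms), 0.0)
    return U * scale


def l21_objective(U: np.ndarray, Xs: list[np.ndarray], y: np.ndarray, lam_eff: float) -> float:
    resid = sum(0.5 * np.sum((X @ U[:, j] - y) ** 2) for j, X in enumerate(Xs))
    return float(resid + lam_eff * np.linalg.norm(U, axis=1).sum())


def _gram_mul(Gt: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Per-view G_v u_v as a (d, views) matrix; Gt is (views, d, d)."""
    return (Gt @ U.T[:, :, None])[:, :, 0].T


def _obj_gram(U: np.ndarray, Gt: np.ndarray, B: np.ndarray, yty: float, lam_eff: float) -> float:
    # 1/2 sum_v (u_v^T G_v u_v - 2 b_v^T u_v + y^T y) + lam ||U||_{2,1}
    quad = float(np.sum(U * _gram_mul(Gt, U)))
    smooth = 0.5 * (quad + U.shape[1] * yty) - float(np.sum(B * U))
    return smooth + lam_eff * float(np.linalg.norm(U, axis=1).sum())


def _grad_gram(U: np.ndarray, Gt: np.ndarray, B: np.ndarray) -> np.ndarray:
    return _gram_mul(Gt, U) - B


def l21_solve(
    views: list[ViewFeatures],
    lam: float,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> MultiViewWeights:
    """Solve the multi-view L2,1 problem at penalty fraction `lam`.

    `lam` is a fraction of :func:`lambda_max` in [0, 1]. Stops when the
    relative objective change drops below `tol` or `max_iter` is reached.
    """
    Xs, y = _stack(views)
    d = Xs[0].shape[1]
    n_views = len(Xs)
    lmax = lambda_max(views)
    lam_eff = lam * lmax
    if lam >= 1.0 or lmax == 0.0:
        U = np.zeros((d, n_views))
        obj = l21_objective(U, Xs, y, lam_eff)
        return MultiViewWeights(U, lam, lmax, np.array([obj]), True)

    # per-view Gram matrices make gradient and objective O(d^2) per view
    G = np.stack([X.T @ X for X in Xs], axis=0)  # (views, d, d)
    B = np.column_stack([X.T @ y for X in Xs])  # (d, views)
    yty = float(y @ y)
    L = max(float(np.linalg.eigvalsh(G[v])[-1]) for v in range(n_views))
    if L <= 0:
        raise ValueError("degenerate views: zero Gram matrix")
    step = 1.0 / L

    U = np.zeros((d, n_views))
    Z = U.copy()
    t_mom = 1.0
    trace = [_obj_gram(U, G, B, yty, lam_eff)]
    converged = False
    for _ in range(max_iter):
        U_new = l21_prox(Z - step * _grad_gram(Z, G, B), step * lam_eff)
        obj_new = _obj_gram(U_new, G, B, yty, lam_eff)
        if not np.isfinite(obj_new):
            raise FloatingPointError("objective diverged; step-size failure")
        if obj_new > trace[-1]:
            # function-value restart: fall back to a plain proximal step
            U_new = l21_prox(U - step * _grad_gram(U, G, B), step * lam_eff)
            obj_new = _obj_gram(U_new, G, B, yty, lam_eff)
            t_mom = 1.0
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        Z = U_new + ((t_mom - 1.0) / t_new) * (U_new - U)
        U, t_mom = U_new, t_new
        trace.append(obj_new)
        denom = max(abs(trace[-2]), 1e-12)
        if abs(trace[-2] - trace[-1]) / denom < tol:
            converged = True
            break
    return MultiViewWeights(U, lam, lmax, np.asarray(trace), converged)
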