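"""Least squares over the probability simplex.

The mixture-weight estimation problem is

    minimize   ||A w - y||^2
    subject to sum(w) = 1,  w >= 0,

a convex quadratic program in a small number of variables (typically 10-25
mixture components).  The solver first obtains the active set from a
non-negative least-squares solve of the penalty-augmented system
[A; rho 1'] w ~ [y; rho] (which enforces the sum constraint to o(1/rho)),
then polishes with an exact equality-constrained KKT solve on that support
and a few primal active-set steps.  A sequential-quadratic-programming
fallback covers degenerate instances (e.g. exactly duplicated columns).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import LinAlgError
from scipy.optimize import minimize, nnls


def _solve_kkt(G: np.ndarray, c: np.ndarray, free: np.ndarray):
    """Equality-constrained minimizer of w'Gw/2 - c'w with sum(w_free)=1.

    Returns the solution on ``free`` and the multiplier of the sum
    constraint; falls back to least squares if the KKT system is singular.
    """
    k = free.size
    M = np.empty((k + 1, k + 1))
    M[:k, :k] = G[np.ix_(free, free)]
    M[:k, k] = 1.0
    M[k, :k] = 1.0
    M[k, k] = 0.0
    rhs = np.empty(k + 1)
    rhs[:k] = c[free]
    rhs[k] = 1.0
    try:
        sol = np.linalg.solve(M, rhs)
        if not np.all(np.isfinite(sol)):
            raise LinAlgError
    except (LinAlgError, np.linalg.LinAlgError):
        sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
    return sol[:k], sol[k]


def _active_set(
    G: np.ndarray,
    c: np.ndarray,
    free: np.ndarray,
    w: np.ndarray,
    tol: float,
    max_iter: int,
):
    """Primal active-set refinement from a feasible start.

    ``free`` indexes the working set (components allowed positive); ``w``
    is a feasible simplex point supported on ``free``.  Returns the
    refined solution or None if the iteration budget is exhausted.
    """
    n = c.size
    scale = max(float(np.max(np.abs(G))), float(np.max(np.abs(c))), 1.0)
    atol = tol * scale
    for _ in range(max_iter):
        z_free, lam = _solve_kkt(G, c, free)
        if np.all(z_free >= -tol):
            w = np.zeros(n)
            w[free] = np.clip(z_free, 0.0, None)
            w /= w.sum()
            g = G @ w - c
            mask = np.ones(n, dtype=bool)
            mask[free] = False
            if not mask.any():
                return w
            viol = g - lam
            viol[~mask] = np.inf
            j = int(np.argmin(viol))
            if viol[j] >= -atol:
                return w
            free = np.sort(np.append(free, j))
        else:
            w_free = w[free]
            d = z_free - w_free
            neg = z_free < 0
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(
                    neg, w_free / np.maximum(w_free - z_free, 1e-300), np.inf
                )
            alpha = min(max(float(np.min(ratios)), 0.0), 1.0)
            w_free = w_free + alpha * d
            w = np.zeros(n)
            w[free] = np.clip(w_free, 0.0, None)
            keep = w[free] > tol
            if not np.any(keep):
                keep[int(np.argmax(z_free))] = True
            free = free[keep]
            s = w.sum()
            if s > 0:
                w /= s
    return None


def _slsqp(G: np.ndarray, c: np.ndarray, w0: np.ndarray) -> np.ndarray:
    """SQP fallback for degenerate instances."""
    n = c.size
    res = minimize(
        lambda w: 0.5 * w @ G @ w - c @ w,
        w0,
        jac=lambda w: G @ w - c,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(n)}],
        options={"maxiter": 300, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def simplex_lsq_normal(
    G: np.ndarray,
    c: np.ndarray,
    tol: float = 1e-10,
    free0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize w'Gw/2 - c'w over the probability simplex (normal-equation form)."""
    n = c.size
    if n == 1:
        return np.ones(1)
    if free0 is None:
        free0 = np.arange(n)
    if w0 is None:
        w0 = np.zeros(n)
        w0[free0] = 1.0 / free0.size
    w = _active_set(G, c, free0.copy(), w0.copy(), tol, max_iter=4 * n + 40)
    if w is None and free0.size < n:  # restart from the full working set
        w = _active_set(
            G, c, np.arange(n), np.full(n, 1.0 / n), tol, max_iter=4 * n + 40
        )
    if w is None:
        w = _slsqp(G, c, w0)
    return w


def _polish(G, c, free, w_best, f_best, tol, max_rounds=15):
    """Bounded KKT refinement of an NNLS solution.

    Alternates equality-constrained solves on the working set with single
    dual-violation additions, keeping the best feasible iterate seen; the
    round cap prevents cycling on near-duplicate columns.
    """
    n = c.size
    scale = max(float(np.max(np.abs(G))), float(np.max(np.abs(c))), 1.0)
    atol = 1e-9 * scale
    for _ in range(max_rounds):
        z, lam = _solve_kkt(G, c, free)
        if np.any(z < -tol):
            keep = z > tol
            if not np.any(keep):
                break
            free = free[keep]
            continue
        w = np.zeros(n)
        w[free] = np.clip(z, 0.0, None)
        w /= w.sum()
        f = w @ (G @ w) - 2.0 * (c @ w)
        if f < f_best:
            w_best, f_best = w, f
        g = G @ w - c
        viol = g - lam
        viol[free] = np.inf
        j = int(np.argmin(viol))
        if viol[j] >= -atol:
            break
        free = np.append(free, j)
    return w_best, f_best


def fit_simplex_weights(A: np.ndarray, y: np.ndarray, tol: float = 1e-10):
    """Solve min ||A w - y||^2 on the simplex; return (w, objective)."""
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n = A.shape[1]
    if n == 1:
        r = A[:, 0] - y
        return np.ones(1), float(r @ r)
    G = A.T @ A
    c = A.T @ y
    # support detection via penalty-augmented NNLS (compiled, fast); the
    # penalty enforces the sum constraint to o(1/rho^2)
    rho = 1000.0 * max(float(np.abs(A).max()), 1.0)
    A_aug = np.vstack([A, np.full((1, n), rho)])
    y_aug = np.append(y, rho)
    try:
        w_nnls, _ = nnls(A_aug, y_aug)
        s = w_nnls.sum()
    except Exception:
        s = 0.0
    if s > 0:
        w0 = w_nnls / s
        free0 = np.flatnonzero(w0 > 1e-12)
        if free0.size == 0:
            free0 = np.arange(n)
        f0 = w0 @ (G @ w0) - 2.0 * (c @ w0)
        w, _ = _polish(G, c, free0, w0, f0, tol)
    else:
        w = simplex_lsq_normal(G, c, tol=tol)
    resid = A @ w - y
    return w, float(resid @ resid)
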