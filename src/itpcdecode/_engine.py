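"""Compiled inner solvers for the decoding pipeline's hot loop.

The permutation test refits the full pipeline (Lasso path inside
cross-validation, then logistic regression) hundreds of thousands of
times on small matrices, where per-call overhead — not arithmetic —
dominates the cost of general-purpose estimators.  This module provides
the two fits as compact compiled kernels:

* :func:`lasso_path_gram` — coordinate descent over a descending penalty
  path on the Gram matrix, minimizing the standard Lasso objective
  ``(1/2n)‖y − Xw‖² + α‖w‖₁`` (no intercept; callers center ``y``).
* :func:`logistic_newton` — damped Newton for l2-penalized logistic
  regression ``½‖w‖² + C Σ log(1 + exp(−y(Xw + b)))`` with an
  unpenalized intercept.

Both match the corresponding scikit-learn estimators on the same
objectives; the test suite holds the two engines equivalent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lasso_path_gram", "logistic_newton"]


@njit(cache=True)
def _sweep(G, c, w, q, thr, active_only, active):  # pragma: no cover - compiled
    """One coordinate-descent sweep; q tracks G @ w incrementally."""
    k = G.shape[0]
    max_change = 0.0
    for j in range(k):
        if active_only and not active[j]:
            continue
        gjj = G[j, j]
        if gjj <= 0.0:
            continue
        rho = c[j] - q[j] + gjj * w[j]
        if rho > thr:
            wj = (rho - thr) / gjj
        elif rho < -thr:
            wj = (rho + thr) / gjj
        else:
            wj = 0.0
        delta = wj - w[j]
        if delta != 0.0:
            for l in range(k):
                q[l] += G[l, j] * delta
            w[j] = wj
            active[j] = wj != 0.0
            if abs(delta) > max_change:
                max_change = abs(delta)
    return max_change


@njit(cache=True)
def _cd_path(G, c, n, alphas, tol, max_iter):  # pragma: no cover - compiled
    k = G.shape[0]
    n_alphas = len(alphas)
    coefs = np.zeros((k, n_alphas))
    w = np.zeros(k)
    q = np.zeros(k)  # G @ w, maintained incrementally
    active = np.zeros(k, dtype=np.bool_)
    for a in range(n_alphas):
        thr = n * alphas[a]
        for _ in range(max_iter):
            # full sweep updates the active set and checks convergence
            if _sweep(G, c, w, q, thr, False, active) < tol:
                break
            # then iterate cheaply on the active set only
            for _inner in range(max_iter):
                if _sweep(G, c, w, q, thr, True, active) < tol:
                    break
        coefs[:, a] = w
    return coefs


def lasso_path_gram(
    X: np.ndarray,
    y_centered: np.ndarray,
    alphas: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> np.ndarray:
    """Lasso coefficients at each penalty of a descending path.

    Gram-based coordinate descent with warm starts along the path;
    returns ``(n_features, n_alphas)``.  ``y_centered`` must be
    mean-removed (the intercept is handled by the caller).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y_centered = np.ascontiguousarray(y_centered, dtype=np.float64)
    G = X.T @ X
    c = X.T @ y_centered
    return _cd_path(G, c, float(len(y_centered)), np.asarray(alphas, dtype=np.float64),
                    tol, max_iter)


@njit(cache=True)
def _newton(X, y, C, tol, max_iter):  # pragma: no cover - compiled
    n, k = X.shape
    theta = np.zeros(k + 1)  # weights + intercept (last)
    for _ in range(max_iter):
        z = X @ theta[:k] + theta[k]
        m = -y * z
        # stable log1p(exp(m)) pieces
        p = np.empty(n)
        for i in range(n):
            if m[i] > 0:
                p[i] = 1.0 / (1.0 + np.exp(-m[i]))
            else:
                e = np.exp(m[i])
                p[i] = e / (1.0 + e)
        # gradient
        grad = np.zeros(k + 1)
        grad[:k] = theta[:k]
        for i in range(n):
            gi = -C * y[i] * p[i]
            for j in range(k):
                grad[j] += gi * X[i, j]
            grad[k] += gi
        # Hessian
        H = np.zeros((k + 1, k + 1))
        for j in range(k):
            H[j, j] = 1.0
        for i in range(n):
            d = C * p[i] * (1.0 - p[i])
            for j in range(k):
                for l in range(k):
                    H[j, l] += d * X[i, j] * X[i, l]
                H[j, k] += d * X[i, j]
                H[k, j] += d * X[i, j]
            H[k, k] += d
        step = np.linalg.solve(H, grad)
        # backtracking on the objective
        obj0 = 0.5 * np.dot(theta[:k], theta[:k])
        for i in range(n):
            if m[i] > 0:
                obj0 += C * (m[i] + np.log1p(np.exp(-m[i])))
            else:
                obj0 += C * np.log1p(np.exp(m[i]))
        t = 1.0
        for _bt in range(30):
            cand = theta - t * step
            z = X @ cand[:k] + cand[k]
            obj = 0.5 * np.dot(cand[:k], cand[:k])
            for i in range(n):
                mi = -y[i] * z[i]
                if mi > 0:
                    obj += C * (mi + np.log1p(np.exp(-mi)))
                else:
                    obj += C * np.log1p(np.exp(mi))
            if obj <= obj0:
                theta = cand
                break
            t *= 0.5
        if np.max(np.abs(t * step)) < tol:
            break
    return theta


def logistic_newton(
    X: np.ndarray, y_pm1: np.ndarray, C: float = 1.0,
    tol: float = 1e-10, max_iter: int = 50,
) -> tuple[np.ndarray, float]:
    """l2-penalized logistic regression via damped Newton iterations.

    ``y_pm1`` holds ±1 labels.  Returns ``(weights, intercept)`` for the
    objective ``½‖w‖² + C Σᵢ log(1 + exp(−yᵢ(xᵢ·w + b)))`` (intercept
    unpenalized) — the same convention as scikit-learn's
    ``LogisticRegression(penalty="l2")``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y_pm1, dtype=np.float64)
    theta = _newton(X, y, float(C), tol, max_iter)
    return theta[:-1], float(theta[-1])
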