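"""Weighted logistic regression with offsets via Newton-Raphson IRLS.

The per-cluster targeting loops fit thousands of tiny logistic models
(n ~ 30-200, p <= 5), including the fluctuation submodels that need an
offset and observation weights.  A compact IRLS solver keeps those loops
fast; its coefficients are cross-checked against statsmodels GLM in the
test suite.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

# linear predictors are clipped to keep expit away from exact 0/1
_LP_MAX = 30.0


class GLMError(RuntimeError):
    """Raised when a logistic fit cannot be completed."""


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fit a logistic model ``logit P(y=1) = offset + X @ beta``.

    ``y`` may be fractional in [0, 1] (quasi-binomial working model).
    Observation ``weights`` multiply the log-likelihood.  On failure to
    converge (e.g. separation) the fit is retried with a small ridge
    penalty; a second failure raises :class:`GLMError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if np.any(w < 0):
        raise GLMError("negative weights")

    beta = _irls(X, y, w, off, ridge, max_iter, tol)
    if beta is None and ridge == 0.0:
        warnings.warn(
            "logistic fit did not converge; retrying with ridge penalty",
            stacklevel=2,
        )
        beta = _irls(X, y, w, off, 1e-4, max_iter, tol)
    if beta is None:
        raise GLMError("logistic fit failed to converge")
    return beta


def _irls(X, y, w, off, ridge, max_iter, tol):
    n, p = X.shape
    beta = np.zeros(p)
    pen = ridge * np.eye(p)
    for _ in range(max_iter):
        lp = np.clip(off + X @ beta, -_LP_MAX, _LP_MAX)
        mu = expit(lp)
        score = X.T @ (w * (y - mu)) - ridge * beta
        wvar = w * mu * (1.0 - mu)
        hess = (X.T * wvar) @ X + pen
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        # step-halving keeps the update inside the region where the
        # quadratic approximation is trustworthy
        for _ in range(30):
            cand = beta + step
            if np.max(np.abs(cand)) < 1e3:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    # non-convergence: accept if the score is essentially solved
    lp = np.clip(off + X @ beta, -_LP_MAX, _LP_MAX)
    score = X.T @ (w * (y - expit(lp))) - ridge * beta
    if np.max(np.abs(score)) < 1e-6 * max(1.0, float(np.sum(w))):
        return beta
    return None


def predict_logistic(
    X: np.ndarray, beta: np.ndarray, offset: np.ndarray | None = None
) -> np.ndarray:
    """Predicted probabilities for a fitted logistic model."""
    X = np.asarray(X, dtype=float)
    lp = X @ beta
    if offset is not None:
        lp = lp + offset
    return expit(np.clip(lp, -_LP_MAX, _LP_MAX))


def fluctuate_intercept(
    offset_logit: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-12,
) -> float:
    """Solve the intercept-only logistic fluctuation.

    Finds epsilon with sum_i w_i (y_i - expit(offset_i + eps)) = 0.
    The score is strictly decreasing in eps, so Newton iterations with a
    bisection fallback always converge.
    """
    off = np.asarray(offset_logit, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.sum(w) <= 0:
        raise GLMError("fluctuation requires positive total weight")

    def score(eps):
        return float(np.sum(w * (y - expit(np.clip(off + eps, -_LP_MAX, _LP_MAX)))))

    eps = 0.0
    for _ in range(100):
        s = score(eps)
        mu = expit(np.clip(off + eps, -_LP_MAX, _LP_MAX))
        d = float(np.sum(w * mu * (1.0 - mu)))
        if d <= 0:
            break
        step = s / d
        step = float(np.clip(step, -5.0, 5.0))
        eps += step
        if abs(step) < tol:
            return eps
    # monotone bisection fallback on a wide bracket
    lo, hi = -_LP_MAX, _LP_MAX
    if score(lo) < 0 or score(hi) > 0:
        # weighted mean of y outside the attainable range; saturate
        return lo if score(lo) < 0 else hi
    from scipy.optimize import brentq

    return float(brentq(score, lo, hi, xtol=tol))
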