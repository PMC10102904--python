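"""Cross-validation-based learner selection for the Stage-1 nuisance fits.

The per-cluster TMLE needs predictions of the outcome regression
E(Y | Delta=1, W, M) and the measurement mechanism P(Delta=1 | W, M).
Both are estimated with a small Super Learner: candidate learners are
scored by V-fold cross-validated negative log-likelihood and either the
single best learner is kept (discrete selection, the default) or a
convex combination of learners is formed by minimizing the CV loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import xlogy

from ._glm import GLMError, fit_logistic, predict_logistic

PRED_BOUNDS = (1e-4, 1.0 - 1e-4)


class MeanLearner:
    """Empirical mean of the outcome, ignoring covariates."""

    name = "mean"

    def fit(self, X, y):
        self.p_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.p_)


class LogisticLearner:
    """Main-terms logistic regression working model."""

    name = "logistic"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        design = np.column_stack([np.ones(X.shape[0]), X])
        self.beta_ = fit_logistic(design, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return predict_logistic(
            np.column_stack([np.ones(X.shape[0]), X]), self.beta_
        )


class SmoothAdditiveLearner:
    """Additive logistic model with cubic B-spline terms.

    Each covariate enters through a cubic B-spline basis with an
    interior knot at its median; a covariate with fewer than 10 distinct
    values degrades to a linear term, since a smoother on a near-binary
    covariate is unstable.
    """

    name = "smooth"
    min_distinct = 10

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.specs_ = []
        cols = [np.ones(X.shape[0])]
        for j in range(X.shape[1]):
            x = X[:, j]
            if np.unique(x).size < self.min_distinct:
                self.specs_.append(("linear", None))
                cols.append(x)
            else:
                lo, hi = float(x.min()), float(x.max())
                mid = float(np.median(x))
                if not lo < mid < hi:
                    mid = 0.5 * (lo + hi)
                knots = np.r_[[lo] * 4, mid, [hi] * 4]
                self.specs_.append(("spline", (knots, lo, hi)))
                cols.append(self._basis(x, knots, lo, hi))
        design = np.column_stack(cols)
        self.beta_ = fit_logistic(design, y)
        return self

    @staticmethod
    def _basis(x, knots, lo, hi):
        x = np.clip(x, lo, hi)
        b = BSpline.design_matrix(x, knots, 3).toarray()
        return b[:, 1:]  # drop one column; intercept is separate

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        cols = [np.ones(X.shape[0])]
        for j, (kind, info) in enumerate(self.specs_):
            if kind == "linear":
                cols.append(X[:, j])
            else:
                cols.append(self._basis(X[:, j], *info))
        return predict_logistic(np.column_stack(cols), self.beta_)


LEARNER_REGISTRY = {
    "mean": MeanLearner,
    "logistic": LogisticLearner,
    "smooth": SmoothAdditiveLearner,
}

DEFAULT_LIBRARY = ("mean", "logistic", "smooth")


@dataclass
class SuperLearnerSpec:
    """Library and cross-validation settings for one nuisance fit."""

    learners: Sequence[str] = DEFAULT_LIBRARY
    v_folds: int = 5
    combination: str = "discrete"
    bounds: tuple[float, float] = PRED_BOUNDS

    def __post_init__(self):
        if len(self.learners) < 1:
            raise ValueError("need at least one learner")
        if self.v_folds < 2:
            raise ValueError("v_folds must be >= 2")
        if self.combination not in ("discrete", "convex"):
            raise ValueError("combination must be 'discrete' or 'convex'")
        unknown = set(self.learners) - set(LEARNER_REGISTRY)
        if unknown:
            raise ValueError(f"unknown learners: {sorted(unknown)}")

    def make_learners(self):
        return [LEARNER_REGISTRY[name]() for name in self.learners]


@dataclass
class SuperLearnerFit:
    """Fitted ensemble: bounded predictions plus CV diagnostics."""

    learners: list
    weights: np.ndarray
    cv_risks: np.ndarray = field(default=None)
    learner_names: tuple = ()
    bounds: tuple[float, float] = PRED_BOUNDS

    @property
    def selected(self) -> str | None:
        """Name of the single selected learner under discrete selection."""
        active = np.flatnonzero(self.weights > 0)
        if active.size == 1:
            return self.learner_names[active[0]]
        return None

    def predict(self, X) -> np.ndarray:
        lo, hi = self.bounds
        preds = np.zeros(np.asarray(X).shape[0])
        for w, learner in zip(self.weights, self.learners):
            if w > 0:
                preds = preds + w * np.clip(learner.predict(X), lo, hi)
        return np.clip(preds, lo, hi)

    def __call__(self, X) -> np.ndarray:
        return self.predict(X)


def _nll(y, p, bounds):
    p = np.clip(p, *bounds)
    return float(-np.mean(xlogy(y, p) + xlogy(1.0 - y, 1.0 - p)))


def _stratified_folds(y, v, rng):
    """Deal observations into v folds, balancing outcome classes."""
    n = y.shape[0]
    fold = np.empty(n, dtype=int)
    classes = np.unique(y) if np.unique(y).size <= 2 else [None]
    pos = 0
    for cls in classes:
        idx = np.arange(n) if cls is None else np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = (np.arange(idx.size) + pos) % v
        pos += idx.size
    return fold


def fit_super_learner(
    x: np.ndarray,
    y: np.ndarray,
    spec: SuperLearnerSpec | None = None,
    rng: np.random.Generator | None = None,
) -> SuperLearnerFit:
    """Fit the Super Learner for a bounded outcome in [0, 1].

    Returns a fitted predictor whose outputs are bounded inside
    ``spec.bounds``.  A degenerate (constant) outcome yields a constant
    predictor; a learner that fails on any fold is dropped with a
    warning.
    """
    if spec is None:
        spec = SuperLearnerSpec()
    if rng is None:
        rng = np.random.default_rng()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("x and y lengths differ")
    names = tuple(spec.learners)

    if np.all(y == y[0]):
        fit = MeanLearner().fit(x, y)
        return SuperLearnerFit(
            learners=[fit], weights=np.array([1.0]),
            learner_names=("mean",), bounds=spec.bounds,
        )

    if len(names) == 1:
        learner = spec.make_learners()[0].fit(x, y)
        return SuperLearnerFit(
            learners=[learner], weights=np.array([1.0]),
            learner_names=names, bounds=spec.bounds,
        )

    v = min(spec.v_folds, n)
    folds = _stratified_folds(y, v, rng)
    k = len(names)
    cv_pred = np.full((n, k), np.nan)
    alive = np.ones(k, dtype=bool)
    for f in range(v):
        tr, te = folds != f, folds == f
        if not te.any() or np.all(y[tr] == y[tr][0]):
            # degenerate training fold: every learner predicts the constant
            for j in range(k):
                cv_pred[te, j] = float(np.mean(y[tr]))
            continue
        for j, name in enumerate(names):
            if not alive[j]:
                continue
            try:
                fitted = LEARNER_REGISTRY[name]().fit(x[tr], y[tr])
                cv_pred[te, j] = fitted.predict(x[te])
            except (GLMError, np.linalg.LinAlgError) as exc:
                warnings.warn(
                    f"learner {name!r} failed on a CV fold ({exc}); dropped",
                    stacklevel=2,
                )
                alive[j] = False
    if not alive.any():
        alive[names.index("mean") if "mean" in names else 0] = True
        cv_pred[:, alive] = float(np.mean(y))

    risks = np.array(
        [_nll(y, cv_pred[:, j], spec.bounds) if alive[j] else np.inf
         for j in range(k)]
    )

    if spec.combination == "discrete":
        weights = np.zeros(k)
        weights[int(np.argmin(risks))] = 1.0
    else:
        weights = _convex_weights(y, cv_pred, alive, spec.bounds)

    fitted = []
    for j, name in enumerate(names):
        if weights[j] > 0:
            fitted.append(LEARNER_REGISTRY[name]().fit(x, y))
        else:
            fitted.append(None)
    return SuperLearnerFit(
        learners=fitted, weights=weights, cv_risks=risks,
        learner_names=names, bounds=spec.bounds,
    )


def _convex_weights(y, cv_pred, alive, bounds):
    k = cv_pred.shape[1]
    idx = np.flatnonzero(alive)
    p = np.clip(cv_pred[:, idx], *bounds)

    def loss(w):
        combo = np.clip(p @ w, *bounds)
        return -np.mean(xlogy(y, combo) + xlogy(1.0 - y, 1.0 - combo))

    w0 = np.full(idx.size, 1.0 / idx.size)
    res = minimize(
        loss, w0, method="SLSQP",
        bounds=[(0.0, 1.0)] * idx.size,
        constraints={"type": "eq", "fun": lambda w: np.sum(w) - 1.0},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum() if w.sum() > 0 else w0
    w[w < 1e-8] = 0.0
    w = w / w.sum()
    full = np.zeros(k)
    full[idx] = w
    return full
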