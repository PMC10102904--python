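"""Stage 2: cluster-level TMLE with Adaptive Prespecification.

The trial is reduced to one record per cluster, O^c = (E^c, W^c, A^c,
Yhat^c), with Yhat^c the Stage-1 endpoint estimate.  The treatment-
specific mean psi(a) = E[E(Yhat^c | A^c=a, E^c, W^c)] is estimated by a
TMLE: a working logistic outcome regression on the [0,1]-scaled
endpoint is fluctuated with the two clever covariates A^c/g^c and
(1-A^c)/(1-g^c), where g^c is the cluster-level propensity score (the
known randomization probability unless an adjusted working model is
selected).  Effects are reported as the risk difference psi(1)-psi(0)
or risk ratio psi(1)/psi(0).

Adaptive Prespecification selects, from a prespecified candidate set,
the single-covariate working models for the outcome regression and the
propensity score whose TMLE has the lowest cross-validated variance of
the estimated influence curve (leave-one-out over clusters, or over
pairs when the matched randomization is preserved).  The unadjusted
estimator is always among the candidates, so the procedure can only
match or improve on it by this criterion.

Inference uses the sample variance of the estimated influence curve
over the N independent units (clusters, or matched pairs when keeping
the matches) with a Student's t reference: N-2 degrees of freedom
unmatched, J-1 over J pairs matched.  Risk ratios are handled on the
log scale via the Delta method and the interval exponentiated.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from ._glm import GLMError, fit_logistic
from .data import ClusterSummary, ValidationError

PS_BOUNDS = (0.1, 0.9)
_Q_BOUNDS = (1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class AdjustmentSpec:
    """Chosen single-covariate working models (None = unadjusted/known)."""

    or_covariate: str | None = None
    ps_covariate: str | None = None


@dataclass
class EffectEstimate:
    """Intervention effect on a chosen scale with IC-based inference.

    ``ic`` holds per-cluster influence-curve contributions on the
    inference scale (natural scale for RD, log scale for RR); its mean
    is zero for the targeted estimator.  ``se`` is on the same scale.
    """

    psi1: float
    psi0: float
    scale: str
    estimate: float
    ic: np.ndarray
    cluster_ids: list
    pair_ids: list
    matched: bool
    selection: AdjustmentSpec
    randomization_prob: float = 0.5
    se: float | None = None
    df: int | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    p_value: float | None = None
    level: float = 0.95
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SelectionResult:
    """Adaptive-Prespecification outcome with CV-variance diagnostics."""

    spec: AdjustmentSpec
    or_cv_variances: dict
    ps_cv_variances: dict

    @property
    def cv_variance(self) -> float:
        return self.ps_cv_variances[self.spec.ps_covariate]

    @property
    def unadjusted_cv_variance(self) -> float:
        return self.or_cv_variances[None]


class _Arrays:
    """Columnar view of the cluster summaries with [0,1] scaling."""

    def __init__(self, summaries: Sequence[ClusterSummary]):
        if len(summaries) < 2:
            raise ValidationError("need at least two clusters")
        self.a = np.array([s.a for s in summaries], dtype=int)
        if self.a.min() == self.a.max():
            raise ValidationError("both treatment arms must be present")
        y = np.array([s.y_c_hat for s in summaries], dtype=float)
        self.lo = min(float(y.min()), 0.0)
        hi = max(float(y.max()), 1.0)
        self.span = hi - self.lo if hi > self.lo else 1.0
        self.y01 = (y - self.lo) / self.span
        self.y = y
        self.cluster_ids = [s.cluster_id for s in summaries]
        self.pair_ids = [s.pair_id for s in summaries]
        self.cov = {}
        names = summaries[0].covariates.keys()
        for name in names:
            self.cov[name] = np.array(
                [s.covariates[name] for s in summaries], dtype=float
            )
        self.n = len(summaries)

    def column(self, name: str | None, idx=None) -> np.ndarray | None:
        if name is None:
            return None
        if name not in self.cov:
            raise ValidationError(f"unknown cluster-level covariate {name!r}")
        col = self.cov[name]
        return col if idx is None else col[idx]

    def pair_folds(self) -> list[np.ndarray]:
        if any(p is None for p in self.pair_ids):
            raise ValidationError("matched analysis requires pair ids")
        groups: dict = {}
        for i, p in enumerate(self.pair_ids):
            groups.setdefault(p, []).append(i)
        for p, members in groups.items():
            if len(members) != 2:
                raise ValidationError(f"pair {p} does not have two clusters")
        return [np.array(m) for m in groups.values()]


class _ORFit:
    """Working outcome regression on the scaled endpoint."""

    def __init__(self, y01, a, cov):
        self.adjusted = cov is not None
        if not self.adjusted:
            # saturated in the arm indicator: fitted values are arm means
            self.mu1 = float(np.mean(y01[a == 1]))
            self.mu0 = float(np.mean(y01[a == 0]))
        else:
            X = np.column_stack([np.ones(a.shape[0]), a, cov])
            self.beta = fit_logistic(X, y01)

    def predict(self, a_val: int, cov, n: int) -> np.ndarray:
        if not self.adjusted:
            mu = self.mu1 if a_val == 1 else self.mu0
            return np.full(n, np.clip(mu, *_Q_BOUNDS))
        X = np.column_stack([np.ones(n), np.full(n, a_val), cov])
        lp = X @ self.beta
        return np.clip(expit(lp), *_Q_BOUNDS)


class _PSFit:
    """Cluster-level propensity score; known probability when unadjusted."""

    def __init__(self, a, cov, prob):
        self.adjusted = cov is not None
        self.prob = prob
        if self.adjusted:
            X = np.column_stack([np.ones(a.shape[0]), cov])
            self.beta = fit_logistic(X, a.astype(float))

    def predict(self, cov, n: int) -> np.ndarray:
        if not self.adjusted:
            return np.full(n, self.prob)
        X = np.column_stack([np.ones(n), cov])
        return np.clip(expit(X @ self.beta), *PS_BOUNDS)


def _fluctuate(y01, a, g, q0_obs) -> np.ndarray:
    """Two-clever-covariate logistic fluctuation; returns (eps1, eps0)."""
    H = np.column_stack([a / g, (1 - a) / (1 - g)])
    offset = logit(np.clip(q0_obs, *_Q_BOUNDS))
    return fit_logistic(H, y01, offset=offset)


def _targeted_predictions(q0_1, q0_0, g, eps):
    qs1 = expit(logit(np.clip(q0_1, *_Q_BOUNDS)) + eps[0] / g)
    qs0 = expit(logit(np.clip(q0_0, *_Q_BOUNDS)) + eps[1] / (1 - g))
    return qs1, qs0


def _combine_ic(ic1, ic0, psi1, psi0, scale):
    if scale == "RD":
        return ic1 - ic0
    if scale == "RR":
        if psi0 == 0 or psi1 == 0:
            raise ValidationError("risk ratio undefined: arm mean is zero")
        return ic1 / psi1 - ic0 / psi0
    raise ValidationError(f"unknown scale {scale!r}")


def _point_and_ic(arr: _Arrays, spec: AdjustmentSpec, scale: str, prob: float):
    a, y01, n = arr.a, arr.y01, arr.n
    or_cov = arr.column(spec.or_covariate)
    ps_cov = arr.column(spec.ps_covariate)
    orf = _ORFit(y01, a, or_cov)
    psf = _PSFit(a, ps_cov, prob)
    g = psf.predict(ps_cov, n)
    q0_1 = orf.predict(1, or_cov, n)
    q0_0 = orf.predict(0, or_cov, n)
    q0_obs = np.where(a == 1, q0_1, q0_0)
    eps = _fluctuate(y01, a, g, q0_obs)
    qs1, qs0 = _targeted_predictions(q0_1, q0_0, g, eps)
    psi1_01, psi0_01 = float(qs1.mean()), float(qs0.mean())
    # back to the original endpoint scale
    psi1 = arr.lo + arr.span * psi1_01
    psi0 = arr.lo + arr.span * psi0_01
    ic1 = arr.span * (a / g * (y01 - qs1) + qs1 - psi1_01)
    ic0 = arr.span * ((1 - a) / (1 - g) * (y01 - qs0) + qs0 - psi0_01)
    ic = _combine_ic(ic1, ic0, psi1, psi0, scale)
    return psi1, psi0, ic, eps


def tmle_effect(
    summaries: Sequence[ClusterSummary],
    spec: AdjustmentSpec | None = None,
    scale: str = "RD",
    matched: bool = False,
    randomization_prob: float = 0.5,
) -> EffectEstimate:
    """Cluster-level TMLE of the intervention effect.

    With the unadjusted spec (None, None) the treatment-specific means
    equal the arm means of the cluster endpoints exactly.  The matched
    flag is carried to :func:`inference`; the point estimate does not
    depend on it.
    """
    if spec is None:
        spec = AdjustmentSpec()
    arr = _Arrays(summaries)
    psi1, psi0, ic, eps = _point_and_ic(arr, spec, scale, randomization_prob)
    if scale == "RD":
        estimate = psi1 - psi0
    else:
        estimate = psi1 / psi0
    return EffectEstimate(
        psi1=psi1,
        psi0=psi0,
        scale=scale,
        estimate=float(estimate),
        ic=ic,
        cluster_ids=arr.cluster_ids,
        pair_ids=arr.pair_ids,
        matched=matched,
        selection=spec,
        randomization_prob=randomization_prob,
        diagnostics={"epsilon": tuple(float(e) for e in eps)},
    )


class _CandidateFailure(Exception):
    pass


def _cv_ic_variance(arr, or_name, ps_name, scale, folds, prob):
    """LOO CV variance of the IC for one candidate working-model pair.

    Held-out clusters' ICs are evaluated at the training-fold nuisance
    fits and the full-data point estimates, then their sample variance
    (pair-averaged first when folds are pairs) is returned.
    """
    psi1_f, psi0_f, _, _ = _point_and_ic(
        arr, AdjustmentSpec(or_name, ps_name), scale, prob
    )
    psi1_01 = (psi1_f - arr.lo) / arr.span
    psi0_01 = (psi0_f - arr.lo) / arr.span
    ic = np.empty(arr.n)
    all_idx = np.arange(arr.n)
    for fold in folds:
        tr = np.setdiff1d(all_idx, fold)
        a_tr, y_tr = arr.a[tr], arr.y01[tr]
        if a_tr.min() == a_tr.max():
            raise _CandidateFailure("training fold contains a single arm")
        try:
            orf = _ORFit(y_tr, a_tr, arr.column(or_name, tr))
            psf = _PSFit(a_tr, arr.column(ps_name, tr), prob)
            g_tr = psf.predict(arr.column(ps_name, tr), tr.size)
            q0_obs = np.where(
                a_tr == 1,
                orf.predict(1, arr.column(or_name, tr), tr.size),
                orf.predict(0, arr.column(or_name, tr), tr.size),
            )
            eps = _fluctuate(y_tr, a_tr, g_tr, q0_obs)
        except (GLMError, np.linalg.LinAlgError) as exc:
            raise _CandidateFailure(str(exc)) from exc
        g_ho = psf.predict(arr.column(ps_name, fold), fold.size)
        qs1, qs0 = _targeted_predictions(
            orf.predict(1, arr.column(or_name, fold), fold.size),
            orf.predict(0, arr.column(or_name, fold), fold.size),
            g_ho,
            eps,
        )
        a_ho, y_ho = arr.a[fold], arr.y01[fold]
        ic1 = arr.span * (a_ho / g_ho * (y_ho - qs1) + qs1 - psi1_01)
        ic0 = arr.span * (
            (1 - a_ho) / (1 - g_ho) * (y_ho - qs0) + qs0 - psi0_01
        )
        ic[fold] = _combine_ic(ic1, ic0, psi1_f, psi0_f, scale)
    if len(folds) < arr.n:  # pair folds: average within pairs first
        units = np.array([ic[f].mean() for f in folds])
    else:
        units = ic
    return float(np.var(units, ddof=1))


def adaptive_prespecification(
    summaries: Sequence[ClusterSummary],
    candidates: Sequence[str] = (),
    scale: str = "RD",
    matched: bool = False,
    randomization_prob: float = 0.5,
    full: bool = False,
) -> AdjustmentSpec | SelectionResult:
    """Select the adjustment working models minimizing CV IC variance.

    Sequential search: first the outcome-regression covariate (with the
    known randomization probability as propensity score), then, holding
    that choice, the propensity-score covariate.  The unadjusted choice
    None is always a candidate and wins ties; remaining ties go to
    candidate-list order.  With fewer than 4 clusters, or if every
    leave-one-out fit for a candidate degenerates, that candidate is
    skipped; if all fail the unadjusted spec is returned with a warning.
    """
    arr = _Arrays(summaries)
    if arr.n < 4:
        warnings.warn(
            "too few clusters for adaptive prespecification; "
            "using the unadjusted estimator",
            stacklevel=2,
        )
        spec = AdjustmentSpec()
        return SelectionResult(spec, {None: np.nan}, {None: np.nan}) if full else spec
    folds = (
        arr.pair_folds()
        if matched
        else [np.array([i]) for i in range(arr.n)]
    )
    choices: list[str | None] = [None] + [c for c in candidates if c is not None]

    def sweep(or_fixed, ps_fixed, vary_or):
        out = {}
        for cand in choices:
            or_name = cand if vary_or else or_fixed
            ps_name = ps_fixed if vary_or else cand
            try:
                out[cand] = _cv_ic_variance(
                    arr, or_name, ps_name, scale, folds, randomization_prob
                )
            except _CandidateFailure as exc:
                warnings.warn(
                    f"candidate {cand!r} dropped during selection: {exc}",
                    stacklevel=3,
                )
        return out

    or_vars = sweep(None, None, vary_or=True)
    if not or_vars:
        warnings.warn(
            "all selection candidates failed; using the unadjusted estimator",
            stacklevel=2,
        )
        spec = AdjustmentSpec()
        return SelectionResult(spec, {None: np.nan}, {None: np.nan}) if full else spec
    best_or = min(or_vars, key=lambda c: (or_vars[c], choices.index(c)))
    ps_vars = sweep(best_or, None, vary_or=False)
    best_ps = min(ps_vars, key=lambda c: (ps_vars[c], choices.index(c)))
    spec = AdjustmentSpec(or_covariate=best_or, ps_covariate=best_ps)
    if full:
        return SelectionResult(spec, or_vars, ps_vars)
    return spec


def inference(
    estimate: EffectEstimate,
    matched: bool | None = None,
    level: float = 0.95,
) -> EffectEstimate:
    """Attach IC-based SE, t-interval and p-value to an estimate.

    Unmatched: variance = sampleVar(IC)/N with N-2 df.  Matched: ICs are
    averaged within pairs, variance = sampleVar(pair IC)/J with J-1 df.
    RR inference is on the log scale; the interval is exponentiated and
    the test is against RR = 1.
    """
    est = copy.deepcopy(estimate)
    if matched is not None:
        est.matched = matched
    est.level = level
    ic = np.asarray(est.ic, dtype=float)
    if est.matched:
        if any(p is None for p in est.pair_ids):
            raise ValidationError("matched inference requires pair ids")
        groups: dict = {}
        for p, v in zip(est.pair_ids, ic):
            groups.setdefault(p, []).append(v)
        units = np.array([np.mean(v) for v in groups.values()])
        df = units.size - 1
    else:
        units = ic
        df = units.size - 2
    if units.size < 2 or df < 1:
        raise ValidationError("fewer than 2 independent units for inference")
    se = float(np.sqrt(np.var(units, ddof=1) / units.size))
    est.se = se
    est.df = int(df)
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
    center = est.estimate if est.scale == "RD" else float(np.log(est.estimate))
    lo, hi = center - tcrit * se, center + tcrit * se
    if se > 0:
        tstat = center / se
        est.p_value = float(2.0 * stats.t.sf(abs(tstat), df))
    else:
        est.p_value = 1.0 if center == 0 else 0.0
    if est.scale == "RR":
        lo, hi = float(np.exp(lo)), float(np.exp(hi))
    est.ci_lo, est.ci_hi = float(lo), float(hi)
    return est
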