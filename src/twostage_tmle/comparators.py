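"""Benchmark comparators: the unadjusted cluster-level t-test and CARE.

Both operate on complete-case cluster means (valid only under MCAR)
and report the risk difference.  CARE (covariate-adjusted residuals
estimator) first fits a pooled individual-level logistic regression of
the outcome on baseline covariates — excluding treatment — among the
measured participants, then t-tests the per-cluster residuals
(observed complete-case mean minus the model's mean prediction over
that cluster's measured participants) by arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._glm import GLMError, fit_logistic, predict_logistic
from .data import ClusterSummary, Trial, ValidationError
from .stage1 import EndpointError


@dataclass
class ComparatorResult:
    """Cluster-level comparator estimate (risk-difference scale)."""

    estimator: str
    estimate: float
    se: float
    df: int
    ci_lo: float
    ci_hi: float
    p_value: float
    matched: bool
    level: float = 0.95


def _t_interval(estimate, se, df, level):
    if se > 0:
        tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
        p = float(2.0 * stats.t.sf(abs(estimate / se), df))
        return estimate - tcrit * se, estimate + tcrit * se, p
    return estimate, estimate, (1.0 if estimate == 0 else 0.0)


def _two_sample_t(vals, arms, welch=False):
    """Pooled-variance two-sample t on cluster-level values, df = N-2."""
    v1, v0 = vals[arms == 1], vals[arms == 0]
    n1, n0 = v1.size, v0.size
    if n1 == 0 or n0 == 0:
        raise ValidationError("both treatment arms must be present")
    estimate = float(v1.mean() - v0.mean())
    if welch:
        s1, s0 = v1.var(ddof=1) / n1, v0.var(ddof=1) / n0
        se = float(np.sqrt(s1 + s0))
        df = int(np.floor((s1 + s0) ** 2 / (s1**2 / (n1 - 1) + s0**2 / (n0 - 1))))
    else:
        sp2 = ((n1 - 1) * v1.var(ddof=1) + (n0 - 1) * v0.var(ddof=1)) / (
            n1 + n0 - 2
        )
        se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0)))
        df = n1 + n0 - 2
    return estimate, se, df


def _paired_t(vals, arms, pair_ids):
    if any(p is None for p in pair_ids):
        raise ValidationError("matched analysis requires pair ids")
    groups: dict = {}
    for v, a, p in zip(vals, arms, pair_ids):
        groups.setdefault(p, {})[a] = v
    diffs = []
    for p, d in groups.items():
        if set(d) != {0, 1}:
            raise ValidationError(f"pair {p} lacks one cluster per arm")
        diffs.append(d[1] - d[0])
    diffs = np.asarray(diffs, dtype=float)
    estimate = float(diffs.mean())
    se = float(np.sqrt(diffs.var(ddof=1) / diffs.size))
    return estimate, se, diffs.size - 1


def ttest_unadjusted(
    summaries: Sequence[ClusterSummary],
    matched: bool = False,
    level: float = 0.95,
    welch: bool = False,
) -> ComparatorResult:
    """t-test contrast of cluster-level endpoints by arm.

    Unmatched: pooled-variance two-sample t with N-2 df (Welch optional
    via flag).  Matched: paired t on within-pair differences, J-1 df.
    """
    vals = np.array([s.y_c_hat for s in summaries], dtype=float)
    arms = np.array([s.a for s in summaries], dtype=int)
    if matched:
        pair_ids = [s.pair_id for s in summaries]
        estimate, se, df = _paired_t(vals, arms, pair_ids)
    else:
        estimate, se, df = _two_sample_t(vals, arms, welch=welch)
    lo, hi, p = _t_interval(estimate, se, df, level)
    return ComparatorResult(
        estimator="ttest", estimate=estimate, se=se, df=df,
        ci_lo=lo, ci_hi=hi, p_value=p, matched=matched, level=level,
    )


def care_estimate(
    trial: Trial,
    covariates: Sequence[str] | None = None,
    matched: bool = False,
    level: float = 0.95,
) -> ComparatorResult:
    """Covariate-adjusted residuals estimator of the risk difference.

    ``covariates`` are individual- and cluster-level baseline covariate
    names (default: every w and e column); the treatment indicator is
    never included.  With an empty covariate list this reduces exactly
    to :func:`ttest_unadjusted` on complete-case cluster means.
    """
    rows_x, rows_y, cluster_slices = [], [], []
    for c in trial.clusters:
        if c.n_measured == 0:
            raise EndpointError(
                f"cluster {c.cluster_id}: no measured outcomes"
            )
        if covariates is None:
            names = list(c.w_names) + list(c.e_names)
        else:
            names = list(covariates)
        meas = c.delta == 1
        cols = []
        for name in names:
            if name in c.w_names:
                cols.append(c.w[meas, c.w_names.index(name)])
            elif name in c.e_names:
                cols.append(np.full(c.n_measured, c.e[c.e_names.index(name)]))
            else:
                raise ValidationError(f"unknown covariate {name!r}")
        x = (
            np.column_stack(cols)
            if cols
            else np.empty((c.n_measured, 0))
        )
        start = sum(len(y) for y in rows_y)
        rows_x.append(x)
        rows_y.append(c.y_measured)
        cluster_slices.append(slice(start, start + c.n_measured))
    X = np.vstack(rows_x)
    y = np.concatenate(rows_y)
    design = np.column_stack([np.ones(X.shape[0]), X])
    try:
        beta = fit_logistic(design, y)
    except GLMError:
        warnings.warn(
            "pooled outcome regression separated; refit with ridge penalty",
            stacklevel=2,
        )
        beta = fit_logistic(design, y, ridge=1e-3)
    preds = predict_logistic(design, beta)

    residuals, arms, pair_ids = [], [], []
    for c, sl in zip(trial.clusters, cluster_slices):
        residuals.append(float(c.y_measured.mean() - preds[sl].mean()))
        arms.append(c.a)
        pair_ids.append(c.pair_id)
    residuals = np.asarray(residuals)
    arms = np.asarray(arms, dtype=int)
    if matched:
        estimate, se, df = _paired_t(residuals, arms, pair_ids)
    else:
        estimate, se, df = _two_sample_t(residuals, arms)
    lo, hi, p = _t_interval(estimate, se, df, level)
    return ComparatorResult(
        estimator="care", estimate=estimate, se=se, df=df,
        ci_lo=lo, ci_hi=hi, p_value=p, matched=matched, level=level,
    )
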