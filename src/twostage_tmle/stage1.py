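"""Stage 1: estimate each cluster's endpoint under complete measurement.

Within one cluster the observed data reduce to O = (W, M, Delta,
Delta*Y) and the target is Y^c = E[E(Y | Delta=1, W, M)], the mean
outcome had every participant been measured.  Each cluster is analyzed
fully separately, so the missingness mechanism may differ arbitrarily
across clusters.

The workhorse is a per-cluster TMLE: an initial Super Learner fit of
the outcome regression among the measured is fluctuated along a
logistic submodel weighted by the inverse of the estimated measurement
probabilities, after which the inverse-probability-weighted residual
(the efficient-influence-function estimating equation) is solved to
numerical precision.  Empirical-mean (MCAR), Kaplan-Meier (survival
endpoints with nondifferential censoring) and ratio-type endpoints
(cross-sectional designs with missingness on the conditioning event)
are provided as alternatives.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from ._glm import GLMError, fluctuate_intercept
from .data import ClusterData, ValidationError
from .superlearner import SuperLearnerFit, SuperLearnerSpec, fit_super_learner

DEFAULT_G_MIN = 0.025
_Q_BOUNDS = (1e-4, 1.0 - 1e-4)


class EndpointError(ValueError):
    """Raised when a cluster endpoint is unidentifiable from the data."""


@dataclass
class Stage1Fit:
    """One cluster's estimated endpoint with targeting diagnostics."""

    y_c_hat: float
    q_star: np.ndarray | None = None
    g: np.ndarray | None = None
    epsilon: float | None = None
    eif_residual: float | None = None
    method: str = "tmle"
    n_truncated: int = 0
    metadata: dict = field(default_factory=dict)


def estimate_endpoint_tmle(
    cluster: ClusterData,
    or_spec: SuperLearnerSpec | None = None,
    g_spec: SuperLearnerSpec | None = None,
    g_min: float = DEFAULT_G_MIN,
    rng: np.random.Generator | None = None,
) -> Stage1Fit:
    """Per-cluster TMLE of Y^c adjusting for (W, M)-driven missingness.

    Steps: (i) outcome regression Qbar0 = E(Y | Delta=1, W, M) via Super
    Learner on the measured participants; (ii) measurement mechanism
    g = P(Delta=1 | W, M) via Super Learner on everyone, truncated below
    at ``g_min``; (iii) intercept-only logistic fluctuation with offset
    logit(Qbar0) and weights 1/g on the measured; (iv) endpoint =
    mean of the targeted predictions over all S^c participants.
    """
    if rng is None:
        rng = np.random.default_rng()
    meas = cluster.delta == 1
    n_meas = int(meas.sum())
    if n_meas == 0:
        raise EndpointError(
            f"cluster {cluster.cluster_id}: no measured outcomes; "
            "endpoint is unidentifiable"
        )
    y = np.asarray(cluster.y_measured, dtype=float)
    lo, hi = float(np.min(y)), float(np.max(y))
    scale = not (lo >= 0.0 and hi <= 1.0)
    if scale:
        span = hi - lo if hi > lo else 1.0
        y = (y - lo) / span

    X = cluster.covariate_matrix()
    q_fit = fit_super_learner(X[meas], y, or_spec, rng)
    q0 = q_fit.predict(X)

    if meas.all():
        g = np.ones(cluster.size)
        g_sl: SuperLearnerFit | None = None
    else:
        try:
            g_sl = fit_super_learner(X, cluster.delta.astype(float), g_spec, rng)
            g = g_sl.predict(X)
        except (GLMError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"cluster {cluster.cluster_id}: measurement-mechanism fit "
                f"failed ({exc}); falling back to the empirical measured "
                "fraction",
                stacklevel=2,
            )
            g_sl = None
            g = np.full(cluster.size, n_meas / cluster.size)
    n_trunc = int(np.sum(g < g_min))
    g = np.clip(g, g_min, 1.0)

    q0_logit = logit(np.clip(q0, *_Q_BOUNDS))
    eps = fluctuate_intercept(q0_logit[meas], y, 1.0 / g[meas])
    q_star = expit(q0_logit + eps)

    resid = np.zeros(cluster.size)
    resid[meas] = (y - q_star[meas]) / g[meas]
    eif_residual = float(resid.mean())

    y_c_hat = float(q_star.mean())
    if scale:
        y_c_hat = lo + y_c_hat * span
        q_star = lo + q_star * span
    return Stage1Fit(
        y_c_hat=y_c_hat,
        q_star=q_star,
        g=g,
        epsilon=float(eps),
        eif_residual=eif_residual,
        method="tmle",
        n_truncated=n_trunc,
        metadata={
            "n_measured": n_meas,
            "or_selected": q_fit.selected,
            "g_selected": getattr(g_sl, "selected", None),
            "rescaled": scale,
        },
    )


def estimate_endpoint_mean(cluster: ClusterData) -> Stage1Fit:
    """Complete-case empirical mean endpoint (valid under MCAR only)."""
    if cluster.n_measured == 0:
        raise EndpointError(
            f"cluster {cluster.cluster_id}: no measured outcomes"
        )
    return Stage1Fit(
        y_c_hat=float(np.mean(cluster.y_measured)),
        method="mean",
        metadata={"assumes": "MCAR", "n_measured": cluster.n_measured},
    )


def estimate_endpoint_km(
    times: np.ndarray, events: np.ndarray, horizon: float
) -> Stage1Fit:
    """Kaplan-Meier cumulative risk by ``horizon`` for one cluster.

    Appropriate for survival endpoints when right-censoring is
    nondifferential.  ``events`` is 1 for failures, 0 for censoring.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EndpointError("no individuals at risk before the horizon")
    if np.any(times < 0):
        raise ValidationError("negative event times")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    surv = float(km.predict(horizon))
    return Stage1Fit(
        y_c_hat=1.0 - surv,
        method="km",
        metadata={"horizon": horizon, "n": int(times.size)},
    )


def estimate_endpoint_ratio(
    cluster: ClusterData,
    numerator: np.ndarray,
    denominator: np.ndarray,
    or_spec: SuperLearnerSpec | None = None,
    g_spec: SuperLearnerSpec | None = None,
    g_min: float = DEFAULT_G_MIN,
    rng: np.random.Generator | None = None,
) -> Stage1Fit:
    """Ratio-type endpoint for cross-sectional designs.

    ``numerator`` and ``denominator`` are binary indicators over the
    measured participants (the joint event and the conditioning event,
    with numerator <= denominator pointwise, e.g. suppressed-and-
    infected over infected).  Each component mean is estimated with the
    per-cluster TMLE and the endpoint is their ratio.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape[0] != cluster.n_measured or den.shape[0] != cluster.n_measured:
        raise ValidationError("component outcomes must cover measured individuals")
    if np.any(num > den):
        raise ValidationError(
            "numerator event must imply the denominator event"
        )
    fits = {}
    for label, vals in (("numerator", num), ("denominator", den)):
        comp = dataclasses.replace(cluster, y_measured=vals)
        fits[label] = estimate_endpoint_tmle(
            comp, or_spec=or_spec, g_spec=g_spec, g_min=g_min, rng=rng
        )
    den_hat = fits["denominator"].y_c_hat
    if den_hat <= 0:
        raise EndpointError(
            f"cluster {cluster.cluster_id}: denominator estimate is zero; "
            "ratio endpoint unidentifiable"
        )
    return Stage1Fit(
        y_c_hat=fits["numerator"].y_c_hat / den_hat,
        method="ratio",
        metadata={"components": fits},
    )
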