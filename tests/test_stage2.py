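"""Stage-2 TMLE, Adaptive Prespecification, and IC-based inference."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, logit

from twostage_tmle.data import ClusterSummary, ValidationError
from twostage_tmle.stage2 import (
    AdjustmentSpec,
    EffectEstimate,
    adaptive_prespecification,
    inference,
    tmle_effect,
)

from conftest import make_summaries


def _summaries(y, a, e1, pair=None):
    out = []
    for i in range(len(y)):
        out.append(
            ClusterSummary(
                cluster_id=i,
                pair_id=None if pair is None else pair[i],
                a=int(a[i]),
                e={"e1c": float(e1[i])},
                y_c_hat=float(y[i]),
            )
        )
    return out


def test_unadjusted_tmle_equals_arm_means_exactly(rng):
    summaries = make_summaries(rng, n=10)
    y = np.array([s.y_c_hat for s in summaries])
    a = np.array([s.a for s in summaries])
    est = tmle_effect(summaries, AdjustmentSpec(), scale="RD")
    assert est.psi1 == pytest.approx(y[a == 1].mean(), abs=1e-12)
    assert est.psi0 == pytest.approx(y[a == 0].mean(), abs=1e-12)
    assert est.estimate == pytest.approx(
        y[a == 1].mean() - y[a == 0].mean(), abs=1e-12
    )


def test_ic_mean_is_zero_for_any_spec(rng):
    summaries = make_summaries(rng, n=12, matched=True)
    for spec in (
        AdjustmentSpec(),
        AdjustmentSpec("e1c", None),
        AdjustmentSpec("e1c", "e2c"),
        AdjustmentSpec(None, "w1c"),
    ):
        for scale in ("RD", "RR"):
            est = tmle_effect(summaries, spec, scale=scale)
            assert abs(np.mean(est.ic)) < 1e-8


def test_point_estimate_independent_of_matched_flag(rng):
    summaries = make_summaries(rng, n=12, matched=True)
    for spec in (AdjustmentSpec(), AdjustmentSpec("e1c", "e1c")):
        em = tmle_effect(summaries, spec, scale="RD", matched=True)
        eu = tmle_effect(summaries, spec, scale="RD", matched=False)
        assert em.estimate == pytest.approx(eu.estimate, abs=1e-14)


def test_six_cluster_toy_matches_root_finding_oracle():
    # known g = 0.5 decouples the two fluctuation parameters: each is a
    # one-dimensional root of its arm's weighted residual equation
    y = np.array([0.30, 0.55, 0.40, 0.70, 0.62, 0.85])
    a = np.array([1, 1, 1, 0, 0, 0])
    e1 = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
    summaries = _summaries(y, a, e1)

    X = np.column_stack([np.ones(6), a, e1])
    q0 = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    q0_1 = q0.predict(np.column_stack([np.ones(6), np.ones(6), e1]))
    q0_0 = q0.predict(np.column_stack([np.ones(6), np.zeros(6), e1]))

    def score1(eps):
        return np.sum(2.0 * (y[a == 1] - expit(logit(q0_1[a == 1]) + 2 * eps)))

    def score0(eps):
        return np.sum(2.0 * (y[a == 0] - expit(logit(q0_0[a == 0]) + 2 * eps)))

    eps1 = brentq(score1, -10, 10, xtol=1e-14)
    eps0 = brentq(score0, -10, 10, xtol=1e-14)
    psi1 = expit(logit(q0_1) + 2 * eps1).mean()
    psi0 = expit(logit(q0_0) + 2 * eps0).mean()

    est = tmle_effect(summaries, AdjustmentSpec("e1c", None), scale="RD")
    assert est.psi1 == pytest.approx(psi1, abs=1e-8)
    assert est.psi0 == pytest.approx(psi0, abs=1e-8)


def test_single_arm_and_unknown_covariate_errors(rng):
    summaries = make_summaries(rng, n=6)
    solo = [s for s in summaries if s.a == 1]
    with pytest.raises(ValidationError):
        tmle_effect(solo, AdjustmentSpec())
    with pytest.raises(ValidationError):
        tmle_effect(summaries, AdjustmentSpec("nope", None))


# -------------------------------------------------- adaptive prespecification
def test_empty_candidates_select_unadjusted(rng):
    summaries = make_summaries(rng, n=8)
    spec = adaptive_prespecification(summaries, candidates=())
    assert spec == AdjustmentSpec(None, None)


def test_selects_the_predictive_covariate(rng):
    hits = 0
    for _ in range(100):
        e1 = rng.normal(0.5, 0.1, size=30)
        e2 = rng.normal(0.5, 0.1, size=30)
        a = np.r_[np.ones(15), np.zeros(15)].astype(int)
        y = np.clip(0.9 * e1 + rng.normal(0, 0.01, size=30), 0.01, 0.99)
        summaries = [
            ClusterSummary(
                cluster_id=i, a=int(a[i]),
                e={"e1c": float(e1[i]), "e2c": float(e2[i])},
                y_c_hat=float(y[i]),
            )
            for i in range(30)
        ]
        spec = adaptive_prespecification(summaries, ("e1c", "e2c"))
        hits += spec.or_covariate == "e1c"
    assert hits >= 95


@pytest.mark.parametrize("matched", [False, True])
def test_selection_never_beats_unadjusted_on_cv_variance(rng, matched):
    for _ in range(20):
        summaries = make_summaries(rng, n=12, matched=matched)
        sel = adaptive_prespecification(
            summaries, ("e1c", "e2c", "w1c"), matched=matched, full=True
        )
        assert sel.cv_variance <= sel.unadjusted_cv_variance + 1e-12
        assert sel.or_cv_variances[sel.spec.or_covariate] <= (
            sel.or_cv_variances[None] + 1e-12
        )


def test_too_few_clusters_falls_back(rng):
    summaries = make_summaries(rng, n=2)
    with pytest.warns(UserWarning, match="too few"):
        spec = adaptive_prespecification(summaries, ("e1c",))
    assert spec == AdjustmentSpec(None, None)


# ------------------------------------------------------------------ inference
def _manual_estimate(ic, scale="RD", estimate=0.1, pair_ids=None, matched=False):
    n = len(ic)
    return EffectEstimate(
        psi1=0.5, psi0=0.4, scale=scale, estimate=estimate,
        ic=np.asarray(ic, dtype=float), cluster_ids=list(range(n)),
        pair_ids=pair_ids if pair_ids is not None else [None] * n,
        matched=matched, selection=AdjustmentSpec(),
    )


def test_unmatched_se_and_df_formula(rng):
    ic = rng.normal(size=30)
    ic -= ic.mean()
    est = inference(_manual_estimate(ic), matched=False)
    assert est.se == pytest.approx(np.sqrt(np.var(ic, ddof=1) / 30))
    assert est.df == 28


def test_matched_uses_pair_averaged_ic(rng):
    ic = rng.normal(size=10)
    ic -= ic.mean()
    pair_ids = [i // 2 for i in range(10)]
    est = inference(_manual_estimate(ic, pair_ids=pair_ids), matched=True)
    pair_ic = ic.reshape(5, 2).mean(axis=1)
    assert est.se == pytest.approx(np.sqrt(np.var(pair_ic, ddof=1) / 5))
    assert est.df == 4


def test_null_risk_ratio_ci_symmetric_on_log_scale(rng):
    ic = rng.normal(size=20)
    ic -= ic.mean()
    est = inference(_manual_estimate(ic, scale="RR", estimate=1.0))
    assert est.ci_lo * est.ci_hi == pytest.approx(1.0, rel=1e-10)
    assert est.p_value == pytest.approx(1.0)
    assert est.ci_lo <= est.estimate <= est.ci_hi


def test_unadjusted_ic_se_matches_pooled_t_algebra(rng):
    # for the unadjusted TMLE with known g=1/2 and equal arms, the IC
    # variance reproduces the pooled two-sample t-test SE up to the
    # (N-2)/(N-1) degrees-of-freedom ratio
    summaries = make_summaries(rng, n=10)
    y = np.array([s.y_c_hat for s in summaries])
    a = np.array([s.a for s in summaries])
    est = inference(tmle_effect(summaries, AdjustmentSpec()), matched=False)
    ss1 = np.sum((y[a == 1] - y[a == 1].mean()) ** 2)
    ss0 = np.sum((y[a == 0] - y[a == 0].mean()) ** 2)
    sp2 = (ss1 + ss0) / (10 - 2)
    se_t = np.sqrt(sp2 * (1 / 5 + 1 / 5))
    assert est.se**2 == pytest.approx(se_t**2 * (10 - 2) / (10 - 1), rel=1e-10)


def test_ci_widens_with_level(rng):
    summaries = make_summaries(rng, n=10)
    est = tmle_effect(summaries, AdjustmentSpec())
    widths = []
    for level in (0.80, 0.95, 0.99):
        e = inference(est, matched=False, level=level)
        widths.append(e.ci_hi - e.ci_lo)
    assert widths[0] < widths[1] < widths[2]


def test_inference_requires_two_units():
    with pytest.raises(ValidationError):
        inference(_manual_estimate([0.1]), matched=False)
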