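"""Stage-1 endpoints: TMLE targeting, oracles, double robustness, KM, ratio."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from twostage_tmle.data import ClusterData, ValidationError
from twostage_tmle.simulate import DGPConfig, draw_cluster
from twostage_tmle.stage1 import (
    EndpointError,
    estimate_endpoint_km,
    estimate_endpoint_mean,
    estimate_endpoint_ratio,
    estimate_endpoint_tmle,
)
from twostage_tmle.superlearner import SuperLearnerSpec

from conftest import make_cluster

SL = SuperLearnerSpec(learners=("mean", "logistic"))
LOGISTIC_ONLY = SuperLearnerSpec(learners=("logistic",))


def _stratified_cluster():
    """12 individuals, one binary W; measurement depends on W only.

    Stratum W=0: 6 individuals, 3 measured with Y = (1, 0, 0).
    Stratum W=1: 6 individuals, 4 measured with Y = (1, 1, 0, 1).
    Hand G-computation: 0.5 * 1/3 + 0.5 * 3/4 = 13/24.
    """
    w = np.r_[np.zeros(6), np.ones(6)].reshape(-1, 1)
    delta = np.r_[1, 1, 1, 0, 0, 0, 1, 1, 1, 1, 0, 0]
    y = np.r_[1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 1.0]
    return ClusterData(
        cluster_id="strat", a=1, e=[0.0], w=w,
        m=np.zeros((12, 0)), delta=delta, y_measured=y,
    )


def test_complete_measurement_reduces_to_empirical_mean(rng):
    c = make_cluster(rng, size=50, p_measure=1.0)
    tm = estimate_endpoint_tmle(c, or_spec=SL, g_spec=SL, rng=rng)
    em = estimate_endpoint_mean(c)
    assert tm.y_c_hat == pytest.approx(em.y_c_hat, abs=1e-12)
    assert np.all(tm.g == 1.0)


def test_empirical_mean_endpoint(rng):
    c = make_cluster(rng, size=4, p_measure=1.0)
    c.y_measured[:] = [1.0, 0.0, 0.0, 1.0]
    assert estimate_endpoint_mean(c).y_c_hat == 0.5
    single = ClusterData(
        cluster_id=1, a=0, e=[0.0], w=np.zeros((3, 1)), m=np.zeros((3, 1)),
        delta=np.array([0, 1, 0]), y_measured=np.array([1.0]),
    )
    assert estimate_endpoint_mean(single).y_c_hat == 1.0


def test_zero_measured_is_unidentifiable():
    c = ClusterData(
        cluster_id=1, a=0, e=[0.0], w=np.zeros((3, 1)), m=np.zeros((3, 1)),
        delta=np.zeros(3, dtype=int), y_measured=np.zeros(0),
    )
    with pytest.raises(EndpointError):
        estimate_endpoint_tmle(c, rng=np.random.default_rng(0))
    with pytest.raises(EndpointError):
        estimate_endpoint_mean(c)


def test_tmle_matches_stratified_gcomputation_oracle(rng):
    # saturated working models on a single binary covariate: the TMLE
    # must equal the nonparametric G-computation sum_w P(w) E(Y|meas,w)
    c = _stratified_cluster()
    fit = estimate_endpoint_tmle(
        c, or_spec=LOGISTIC_ONLY, g_spec=LOGISTIC_ONLY, g_min=1e-6, rng=rng
    )
    assert fit.y_c_hat == pytest.approx(13 / 24, abs=1e-10)
    assert abs(fit.eif_residual) < 1e-10
    # measurement probabilities recover the stratum fractions 1/2, 2/3
    np.testing.assert_allclose(
        [fit.g.min(), fit.g.max()], [0.5, 2 / 3], atol=1e-6
    )


def test_eif_equation_solved_on_random_clusters(rng):
    for seed in range(8):
        c = make_cluster(
            np.random.default_rng(seed), a=seed % 2, size=60, p_measure=0.6
        )
        fit = estimate_endpoint_tmle(c, or_spec=SL, g_spec=SL, rng=rng)
        assert abs(fit.eif_residual) < 1e-8
        assert 0.0 <= fit.y_c_hat <= 1.0
        assert np.all((fit.g >= 0.025) & (fit.g <= 1.0))


def test_tmle_removes_differential_measurement_bias(rng):
    # one huge intervention-arm cluster from the trial generator: the
    # TMLE endpoint should land near the known counterfactual mean while
    # the complete-case mean stays far away
    cfg = DGPConfig(cluster_size_support=(5000,))
    sc = draw_cluster(cfg, np.random.default_rng(77))
    obs = sc.realize(1, cluster_id=0)
    truth = sc.y_c_true(1)
    fit = estimate_endpoint_tmle(obs, or_spec=SL, g_spec=SL, rng=rng)
    cc = float(obs.y_measured.mean())
    assert abs(fit.y_c_hat - truth) < 0.05
    assert abs(cc - truth) > abs(fit.y_c_hat - truth)


@pytest.mark.parametrize("direction", ["g_correct", "q_correct"])
def test_double_robustness(direction, rng):
    # only one nuisance model family is correct in each direction; the
    # endpoint estimate must still be (nearly) unbiased at large S
    q_true = lambda w: expit(0.3 + 1.5 * w)
    truth = quad(lambda w: q_true(w) * norm.pdf(w), -10, 10)[0]
    if direction == "g_correct":
        g_true = lambda w: expit(1.5 - 1.2 * w)  # logistic: correct family
        q_spec = SuperLearnerSpec(learners=("mean",))  # misspecified
        g_spec = SuperLearnerSpec(learners=("logistic",))
    else:
        g_true = lambda w: expit(1.0 - w**2)  # not constant: mean is wrong
        q_spec = SuperLearnerSpec(learners=("logistic",))  # correct family
        g_spec = SuperLearnerSpec(learners=("mean",))
    errs, cc_errs = [], []
    for _ in range(50):
        s = 5000
        w = rng.normal(size=s)
        delta = (rng.uniform(size=s) < g_true(w)).astype(int)
        y_all = (rng.uniform(size=s) < q_true(w)).astype(float)
        c = ClusterData(
            cluster_id=0, a=0, e=[0.0], w=w.reshape(-1, 1),
            m=np.zeros((s, 0)), delta=delta, y_measured=y_all[delta == 1],
        )
        fit = estimate_endpoint_tmle(
            c, or_spec=q_spec, g_spec=g_spec, g_min=0.01, rng=rng
        )
        errs.append(fit.y_c_hat - truth)
        cc_errs.append(y_all[delta == 1].mean() - truth)
    assert abs(np.mean(errs)) < 0.01
    if direction == "g_correct":
        assert abs(np.mean(cc_errs)) > 0.05  # complete case clearly biased


# ------------------------------------------------------------------ KM
def test_km_no_censoring_is_empirical_proportion():
    fit = estimate_endpoint_km(
        times=[1.0, 10.0, 2.0, 10.0], events=[1, 0, 1, 0], horizon=5.0
    )
    assert fit.y_c_hat == pytest.approx(0.5, abs=1e-12)


def test_km_product_limit_oracle():
    # hand product-limit: S(6) = (1 - 1/3)(1 - 1/1) = 0 -> risk 1
    fit = estimate_endpoint_km(times=[2.0, 4.0, 6.0], events=[1, 0, 1], horizon=6.0)
    assert fit.y_c_hat == pytest.approx(1.0, abs=1e-12)


def test_km_all_censored_gives_zero_risk():
    fit = estimate_endpoint_km(
        times=[1.0, 2.0, 3.0], events=[0, 0, 0], horizon=5.0
    )
    assert fit.y_c_hat == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(EndpointError):
        estimate_endpoint_km(times=[], events=[], horizon=1.0)


# ----------------------------------------------------------------- ratio
def test_ratio_full_measurement_reduces_to_proportion_ratio(rng):
    s = 20
    c = ClusterData(
        cluster_id=0, a=1, e=[0.0], w=rng.normal(size=(s, 1)),
        m=np.zeros((s, 0)), delta=np.ones(s, dtype=int),
        y_measured=np.zeros(s),
    )
    den = np.r_[np.ones(8), np.zeros(12)]   # prevalence 0.40
    num = np.r_[np.ones(6), np.zeros(14)]   # joint 0.30
    fit = estimate_endpoint_ratio(c, num, den, or_spec=SL, g_spec=SL, rng=rng)
    assert fit.y_c_hat == pytest.approx(0.75, abs=1e-6)


def test_ratio_identical_components_is_one(rng):
    # single-learner specs keep the two component fits deterministic
    c = make_cluster(rng, size=30, p_measure=0.8)
    ind = (rng.uniform(size=c.n_measured) < 0.5).astype(float)
    ind[0] = 1.0
    fit = estimate_endpoint_ratio(
        c, ind, ind, or_spec=LOGISTIC_ONLY, g_spec=LOGISTIC_ONLY, rng=rng
    )
    assert fit.y_c_hat == pytest.approx(1.0, abs=1e-10)


def test_ratio_matches_stratified_oracle_twice(rng):
    c = _stratified_cluster()
    den = np.ones(7)
    num = c.y_measured.copy()
    fit = estimate_endpoint_ratio(
        c, num, den, or_spec=LOGISTIC_ONLY, g_spec=LOGISTIC_ONLY, rng=rng
    )
    # denominator G-computation is degenerate at 1, numerator is 13/24
    assert fit.y_c_hat == pytest.approx(13 / 24, abs=1e-6)


def test_ratio_validates_nesting(rng):
    c = make_cluster(rng, size=10, p_measure=1.0)
    num = np.ones(c.n_measured)
    den = np.zeros(c.n_measured)
    with pytest.raises(ValidationError):
        estimate_endpoint_ratio(c, num, den, rng=rng)
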