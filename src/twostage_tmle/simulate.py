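"""Synthetic CRT generator with differential outcome measurement.

Clusters are built from three latent cluster-level variables: two shift
the means of the individual-level baseline covariates (W1, W2) and one
(U3) induces residual dependence within clusters and drives the pair
matching.  A post-baseline binary mediator M is increased by treatment
and in turn raises both the outcome and — differentially by arm — the
chance that the outcome is measured.  Under the defaults roughly 70% of
intervention-arm and 43% of control-arm participants have measured
outcomes, so complete-case analyses are biased.

Counterfactual mediators, outcomes and measurement indicators under
both arms are generated from shared uniform draws, so the observed data
are exactly consistent with the counterfactual at the realized arm and
cluster-level true outcomes are deterministic given the latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data import ClusterData, Trial, ValidationError


def _default_m_coefs() -> dict:
    return {"intercept": -1.0, "a": 2.0, "w1": 1.0, "w2": 1.0,
            "e_control": 0.2, "u3": 0.25}


def _default_y_coefs() -> dict:
    return {"intercept": 1.0, "a": -2.5, "m": 4.0, "w1": 0.5, "w2": 0.5,
            "e1": 0.2, "e2": 0.2, "u3": 0.25}


def _default_d_treated() -> dict:
    return {"intercept": 3.0, "m": -3.0, "w1": -0.5, "w2": -0.5}


def _default_d_control() -> dict:
    return {"intercept": -2.0, "m": 3.0, "w1": 0.5, "w2": 0.5}


@dataclass
class DGPConfig:
    """Configuration of the data-generating process.

    Coefficient dictionaries override single terms of the structural
    equations; ``null_effect`` removes every treatment term from the
    mediator and outcome equations (measurement stays differential), so
    the true risk difference is 0 and the true risk ratio is 1.
    """

    n_clusters: int = 30
    cluster_size_support: Sequence[int] = (100, 150, 200)
    m_coefs: dict = field(default_factory=_default_m_coefs)
    y_coefs: dict = field(default_factory=_default_y_coefs)
    d_coefs_treated: dict = field(default_factory=_default_d_treated)
    d_coefs_control: dict = field(default_factory=_default_d_control)
    null_effect: bool = False
    seed: int | None = None

    def __post_init__(self):
        if any(s <= 0 for s in self.cluster_size_support):
            raise ValidationError("cluster sizes must be positive")
        if self.n_clusters < 1:
            raise ValidationError("need at least one cluster")


@dataclass
class SimulatedCluster:
    """One generated cluster with latents and both-arm counterfactuals.

    ``m_cf``, ``y_cf``, ``d_cf`` are (S, 2) arrays indexed by arm; the
    observed data under an assigned arm are a column slice of these.
    """

    u1c: float
    u2c: float
    u3c: float
    w1: np.ndarray
    w2: np.ndarray
    e1c: float
    e2c: float
    m_cf: np.ndarray
    y_cf: np.ndarray
    d_cf: np.ndarray

    @property
    def size(self) -> int:
        return self.w1.shape[0]

    def y_c_true(self, a: int) -> float:
        """Cluster mean of the counterfactual outcome Y(a, delta=1)."""
        return float(self.y_cf[:, a].mean())

    def realize(self, a: int, cluster_id, pair_id=None) -> ClusterData:
        """Observed cluster data under assigned arm ``a``."""
        d = self.d_cf[:, a]
        y = self.y_cf[:, a]
        return ClusterData(
            cluster_id=cluster_id,
            pair_id=pair_id,
            a=int(a),
            e=np.array([self.e1c, self.e2c]),
            w=np.column_stack([self.w1, self.w2]),
            m=self.m_cf[:, a].reshape(-1, 1).astype(float),
            delta=d,
            y_measured=y[d == 1].astype(float),
            w_names=("w1", "w2"),
            m_names=("m",),
            e_names=("e1c", "e2c"),
        )


@dataclass
class SimulatedTrial:
    """Observed trial plus the generated clusters (for truth bookkeeping)."""

    trial: Trial
    clusters: list[SimulatedCluster]
    arms: np.ndarray


@dataclass
class TruthRecord:
    psi1: float
    psi0: float
    rd: float
    rr: float | None


def draw_cluster(config: DGPConfig, rng: np.random.Generator) -> SimulatedCluster:
    """Generate one cluster with counterfactuals under both arms."""
    size = int(rng.choice(np.asarray(config.cluster_size_support)))
    u1c = rng.uniform(-1.0, 1.0)
    u2c = rng.uniform(-1.0, 1.0)
    u3c = rng.normal(0.0, 1.0)
    w1 = rng.normal(u1c, 0.5, size)
    w2 = rng.normal(u2c, 0.5, size)
    e1c = float(w1.mean())
    e2c = float(w2.mean())
    u_m = rng.uniform(size=size)
    u_y = rng.uniform(size=size)
    u_d = rng.uniform(size=size)

    mc, yc = config.m_coefs, config.y_coefs
    m_cf = np.empty((size, 2), dtype=int)
    y_cf = np.empty((size, 2), dtype=int)
    d_cf = np.empty((size, 2), dtype=int)
    for a in (0, 1):
        # under a null effect the mediator and outcome ignore the arm
        a_my = 0 if config.null_effect else a
        lp_m = (
            mc["intercept"]
            + mc["a"] * a_my
            + mc["w1"] * w1
            + mc["w2"] * w2
            + mc["e_control"] * (1 - a_my) * (e1c + e2c)
            + mc["u3"] * u3c
        )
        m = (u_m < expit(lp_m)).astype(int)
        lp_y = (
            yc["intercept"]
            + yc["a"] * a_my
            + yc["m"] * m
            + yc["w1"] * w1
            + yc["w2"] * w2
            + yc["e1"] * e1c
            + yc["e2"] * e2c
            + yc["u3"] * u3c
        )
        y = (u_y < expit(lp_y)).astype(int)
        dc = config.d_coefs_treated if a == 1 else config.d_coefs_control
        p_d = expit(dc["intercept"] + dc["m"] * m + dc["w1"] * w1 + dc["w2"] * w2)
        d = (u_d < p_d).astype(int)
        m_cf[:, a], y_cf[:, a], d_cf[:, a] = m, y, d

    return SimulatedCluster(
        u1c=u1c, u2c=u2c, u3c=u3c, w1=w1, w2=w2, e1c=e1c, e2c=e2c,
        m_cf=m_cf, y_cf=y_cf, d_cf=d_cf,
    )


def randomize_trial(
    clusters: Sequence[SimulatedCluster],
    matched: bool,
    rng: np.random.Generator,
) -> SimulatedTrial:
    """Randomize treatment and realize the observed trial.

    Matched: clusters are ranked on the matching latent U3 and adjacent
    clusters paired; within each pair one cluster is treated with
    probability 1/2.  Unmatched: a simple 1:1 allocation (exactly half
    the clusters treated, chosen uniformly at random).
    """
    n = len(clusters)
    if matched and n % 2 != 0:
        raise ValidationError("pair-matching requires an even number of clusters")
    arms = np.zeros(n, dtype=int)
    pair_ids: list = [None] * n
    if matched:
        order = np.argsort([c.u3c for c in clusters], kind="stable")
        for p in range(n // 2):
            i, j = order[2 * p], order[2 * p + 1]
            first_treated = rng.integers(2)
            arms[i], arms[j] = first_treated, 1 - first_treated
            pair_ids[i] = pair_ids[j] = p
    else:
        treated = rng.permutation(n)[: n // 2]
        arms[treated] = 1
    observed = [
        c.realize(arms[i], cluster_id=i, pair_id=pair_ids[i])
        for i, c in enumerate(clusters)
    ]
    trial = Trial(clusters=observed, matched=matched)
    return SimulatedTrial(trial=trial, clusters=list(clusters), arms=arms)


def simulate_trial(
    config: DGPConfig, rng: np.random.Generator, matched: bool = True
) -> SimulatedTrial:
    """Draw ``config.n_clusters`` clusters and randomize the trial."""
    clusters = [draw_cluster(config, rng) for _ in range(config.n_clusters)]
    return randomize_trial(clusters, matched=matched, rng=rng)


def compute_truth(
    config: DGPConfig,
    n_population: int = 5000,
    rng: np.random.Generator | None = None,
) -> TruthRecord:
    """True treatment-specific means from a large population of clusters.

    psi_a is the population mean of the cluster-level counterfactual
    outcomes Y^c(a); the risk difference and risk ratio contrast them.
    """
    if n_population < 1:
        raise ValidationError("population must contain at least one cluster")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s1 = s0 = 0.0
    for _ in range(n_population):
        c = draw_cluster(config, rng)
        s1 += c.y_c_true(1)
        s0 += c.y_c_true(0)
    psi1, psi0 = s1 / n_population, s0 / n_population
    rr = psi1 / psi0 if psi0 != 0 else None
    return TruthRecord(psi1=psi1, psi0=psi0, rd=psi1 - psi0, rr=rr)


def measured_fractions(
    config: DGPConfig,
    n_trials: int = 200,
    rng: np.random.Generator | None = None,
    matched: bool = True,
) -> tuple[float, float]:
    """Mean measured proportion by arm, averaged over simulated trials."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fr1, fr0 = [], []
    for _ in range(n_trials):
        sim = simulate_trial(config, rng, matched=matched)
        d1 = np.concatenate(
            [c.delta for c in sim.trial.clusters if c.a == 1]
        )
        d0 = np.concatenate(
            [c.delta for c in sim.trial.clusters if c.a == 0]
        )
        fr1.append(d1.mean())
        fr0.append(d0.mean())
    return float(np.mean(fr1)), float(np.mean(fr0))


def coefficient_of_variation(
    sim: SimulatedTrial, arm: int, kind: str = "true"
) -> float:
    """Between-cluster SD over mean of cluster outcomes in one arm.

    ``kind='true'`` uses the counterfactual cluster means Y^c(arm) of
    the clusters randomized to that arm; ``kind='observed'`` uses the
    complete-case cluster means.
    """
    if kind == "true":
        vals = [
            c.y_c_true(arm)
            for c, a in zip(sim.clusters, sim.arms)
            if a == arm
        ]
    elif kind == "observed":
        vals = [
            float(c.y_measured.mean())
            for c in sim.trial.clusters
            if c.a == arm and c.n_measured > 0
        ]
    else:
        raise ValueError("kind must be 'true' or 'observed'")
    vals = np.asarray(vals, dtype=float)
    return float(vals.std(ddof=1) / vals.mean())
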