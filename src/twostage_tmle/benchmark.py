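"""Repeated-trial benchmark of CRT estimators under the synthetic DGP.

For each replicate a matched-pair trial is generated, each requested
estimator is applied (Two-Stage TMLE on the risk-difference and
risk-ratio scales, the unadjusted t-test and CARE on the risk
difference, each both keeping and breaking the matches), and the
standard operating characteristics are aggregated against the true
effects computed from a large cluster population: mean point estimate,
bias, SD of estimates, mean SE, 95% CI coverage and power.  SD, SE and
bias for the risk ratio are computed on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .comparators import care_estimate, ttest_unadjusted
from .data import summarize_cluster
from .simulate import DGPConfig, TruthRecord, compute_truth, simulate_trial
from .stage1 import estimate_endpoint_tmle
from .stage2 import adaptive_prespecification, inference, tmle_effect
from .superlearner import SuperLearnerSpec

# reduced default library keeps 500 replicates at desk scale; the
# smooth learner can be added back via sl_learners
BENCHMARK_LIBRARY = ("mean", "logistic")
DEFAULT_CANDIDATES = ("e1c", "e2c")


@dataclass
class BenchmarkResult:
    """Aggregated operating characteristics plus per-replicate records."""

    table: pd.DataFrame
    replicates: pd.DataFrame
    truth: TruthRecord
    n_reps: int
    seed: int
    n_failures: dict

    def row(self, estimator: str, scale: str = "RD", matched: bool = False):
        t = self.table
        m = (
            (t.estimator == estimator)
            & (t.scale == scale)
            & (t.matched == matched)
        )
        sub = t[m]
        if len(sub) != 1:
            raise KeyError((estimator, scale, matched))
        return sub.iloc[0]


def run_benchmark(
    config: DGPConfig | None = None,
    estimators: Sequence[str] = ("tmle", "ttest", "care"),
    n_reps: int = 500,
    seed: int = 0,
    scales: Sequence[str] = ("RD", "RR"),
    matched_modes: Sequence[bool] = (True, False),
    sl_learners: Sequence[str] = BENCHMARK_LIBRARY,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    v_folds: int = 5,
    g_min: float = 0.025,
    n_truth: int = 5000,
    truth: TruthRecord | None = None,
) -> BenchmarkResult:
    """Run the simulation benchmark and aggregate the metric table.

    Replicate streams are spawned from a single seed, so results are
    reproducible and independent of which estimators are requested.
    An estimator that fails on a replicate is excluded from its own
    aggregates; failures are counted in ``n_failures``.
    """
    if config is None:
        config = DGPConfig()
    unknown = set(estimators) - {"tmle", "ttest", "care"}
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps + 1)
    if truth is None:
        truth = compute_truth(
            config, n_population=n_truth, rng=np.random.default_rng(children[0])
        )
    sl_spec = SuperLearnerSpec(learners=tuple(sl_learners), v_folds=v_folds)

    rows: list[dict] = []
    failures: dict = {}
    for rep in range(n_reps):
        rng = np.random.default_rng(children[rep + 1])
        sim = simulate_trial(config, rng, matched=True)
        trial = sim.trial

        def record(estimator, scale, matched, res=None, err=None, sel=None):
            row = {
                "rep": rep,
                "estimator": estimator,
                "scale": scale,
                "matched": matched,
            }
            if err is not None:
                row["error"] = str(err)
                key = (estimator, scale, matched)
                failures[key] = failures.get(key, 0) + 1
            else:
                row.update(
                    estimate=res.estimate, se=res.se, ci_lo=res.ci_lo,
                    ci_hi=res.ci_hi, p_value=res.p_value, error=None,
                )
                if sel is not None:
                    row["or_covariate"] = sel.or_covariate
                    row["ps_covariate"] = sel.ps_covariate
            rows.append(row)

        cc_summaries = None
        if "ttest" in estimators or "care" in estimators:
            try:
                cc_summaries = [
                    summarize_cluster(c, float(np.mean(c.y_measured)))
                    for c in trial.clusters
                ]
            except (ValueError, ZeroDivisionError) as exc:
                cc_summaries = exc

        for matched in matched_modes:
            if "ttest" in estimators:
                if isinstance(cc_summaries, Exception):
                    record("ttest", "RD", matched, err=cc_summaries)
                else:
                    try:
                        record(
                            "ttest", "RD", matched,
                            res=ttest_unadjusted(cc_summaries, matched=matched),
                        )
                    except Exception as exc:  # noqa: BLE001 - logged & counted
                        record("ttest", "RD", matched, err=exc)
            if "care" in estimators:
                try:
                    record(
                        "care", "RD", matched,
                        res=care_estimate(trial, matched=matched),
                    )
                except Exception as exc:  # noqa: BLE001
                    record("care", "RD", matched, err=exc)

        if "tmle" in estimators:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    summaries = [
                        summarize_cluster(
                            c,
                            estimate_endpoint_tmle(
                                c, or_spec=sl_spec, g_spec=sl_spec,
                                g_min=g_min, rng=rng,
                            ).y_c_hat,
                        )
                        for c in trial.clusters
                    ]
                for scale in scales:
                    for matched in matched_modes:
                        try:
                            spec = adaptive_prespecification(
                                summaries, candidates, scale=scale,
                                matched=matched,
                            )
                            est = inference(
                                tmle_effect(
                                    summaries, spec, scale=scale, matched=matched
                                ),
                                matched=matched,
                            )
                            record("tmle", scale, matched, res=est, sel=spec)
                        except Exception as exc:  # noqa: BLE001
                            record("tmle", scale, matched, err=exc)
            except Exception as exc:  # noqa: BLE001 - Stage-1 failure
                for scale in scales:
                    for matched in matched_modes:
                        record("tmle", scale, matched, err=exc)

    replicates = pd.DataFrame(rows)
    table = _aggregate(replicates, truth)
    return BenchmarkResult(
        table=table, replicates=replicates, truth=truth,
        n_reps=n_reps, seed=seed, n_failures=failures,
    )


def _aggregate(replicates: pd.DataFrame, truth: TruthRecord) -> pd.DataFrame:
    out = []
    ok = replicates[replicates.error.isna()] if "error" in replicates else replicates
    for (estimator, scale, matched), g in ok.groupby(
        ["estimator", "scale", "matched"], sort=False
    ):
        n = len(g)
        est = g.estimate.to_numpy(dtype=float)
        se = g.se.to_numpy(dtype=float)
        if scale == "RD":
            true_val, null = truth.rd, 0.0
            pt = 100.0 * est.mean()
            bias = 100.0 * (est.mean() - true_val)
            bias_mc = 100.0 * 1.96 * est.std(ddof=1) / np.sqrt(n)
            sd = est.std(ddof=1)
        else:
            true_val, null = truth.rr, 1.0
            pt = est.mean()
            log_est = np.log(est)
            bias = log_est.mean() - np.log(true_val)
            bias_mc = 1.96 * log_est.std(ddof=1) / np.sqrt(n)
            sd = log_est.std(ddof=1)
        cover = np.mean((g.ci_lo <= true_val) & (true_val <= g.ci_hi))
        power = np.mean(g.p_value < 0.05)
        out.append(
            {
                "estimator": estimator,
                "scale": scale,
                "matched": matched,
                "pt": pt,
                "bias": bias,
                "sd": sd,
                "mean_se": se.mean(),
                "coverage": 100.0 * cover,
                "power": 100.0 * power,
                "n_ok": n,
                "bias_mc_halfwidth": bias_mc,
                "coverage_mc_halfwidth": 100.0
                * 1.96
                * np.sqrt(cover * (1 - cover) / n),
                "power_mc_halfwidth": 100.0
                * 1.96
                * np.sqrt(power * (1 - power) / n),
                "true_value": true_val,
                "null_value": null,
            }
        )
    return pd.DataFrame(out)
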