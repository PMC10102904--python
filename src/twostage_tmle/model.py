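"""Model/results interface for Two-Stage TMLE.

`TwoStageTMLE` is constructed from a trial (or a file/DataFrame) and
`fit()` returns a `TwoStageTMLEResults` carrying the effect estimate,
influence-curve-based uncertainty, the selected adjustment working
models, per-cluster endpoint fits and a `summary()` table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data as dm
from .data import ClusterSummary, Trial
from .stage1 import (
    DEFAULT_G_MIN,
    Stage1Fit,
    estimate_endpoint_mean,
    estimate_endpoint_tmle,
)
from .stage2 import (
    AdjustmentSpec,
    EffectEstimate,
    SelectionResult,
    adaptive_prespecification,
    inference,
    tmle_effect,
)
from .superlearner import DEFAULT_LIBRARY, SuperLearnerSpec


class TwoStageTMLE:
    """Two-Stage TMLE for a cluster randomized trial.

    Parameters
    ----------
    trial
        Individual-level trial data (`data.Trial`).
    scale
        "RD" (risk difference) or "RR" (risk ratio).
    matched
        Preserve the matched pairs during selection and inference;
        defaults to the trial's own matched flag.
    candidates
        Cluster-level covariate names offered to Adaptive
        Prespecification; defaults to every cluster-level baseline
        covariate (e columns and w summaries).
    stage1
        "tmle" (per-cluster TMLE adjusting for missingness) or "mean"
        (complete-case empirical mean, MCAR).
    sl_learners, v_folds
        Super Learner library and CV folds for the Stage-1 nuisance
        fits.
    g_min
        Lower truncation for estimated measurement probabilities.
    randomization_prob
        Known cluster-level randomization probability.
    """

    def __init__(
        self,
        trial: Trial,
        scale: str = "RD",
        matched: bool | None = None,
        candidates: Sequence[str] | None = None,
        stage1: str = "tmle",
        sl_learners: Sequence[str] = DEFAULT_LIBRARY,
        v_folds: int = 5,
        g_min: float = DEFAULT_G_MIN,
        randomization_prob: float = 0.5,
    ):
        if scale not in ("RD", "RR"):
            raise ValueError("scale must be 'RD' or 'RR'")
        if stage1 not in ("tmle", "mean"):
            raise ValueError(
                "stage1 must be 'tmle' or 'mean' (survival and ratio "
                "endpoints are available through the stage1 module functions)"
            )
        self.trial = trial
        self.scale = scale
        self.matched = trial.matched if matched is None else matched
        self.candidates = candidates
        self.stage1 = stage1
        self.sl_spec = SuperLearnerSpec(learners=tuple(sl_learners), v_folds=v_folds)
        self.g_min = g_min
        self.randomization_prob = randomization_prob

    @classmethod
    def from_csv(cls, path, schema: Mapping | None = None, **kwargs):
        return cls(dm.read_trial(path, schema=schema), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: Mapping | None = None, **kwargs):
        return cls(dm.trial_from_dataframe(df, schema=schema), **kwargs)

    def fit(self, seed: int | None = None) -> "TwoStageTMLEResults":
        rng = np.random.default_rng(seed)
        stage1_fits: dict = {}
        summaries: list[ClusterSummary] = []
        for c in self.trial.clusters:
            if self.stage1 == "tmle":
                f = estimate_endpoint_tmle(
                    c, or_spec=self.sl_spec, g_spec=self.sl_spec,
                    g_min=self.g_min, rng=rng,
                )
            else:
                f = estimate_endpoint_mean(c)
            stage1_fits[c.cluster_id] = f
            summaries.append(dm.summarize_cluster(c, f.y_c_hat))
        if self.candidates is None:
            cand = list(summaries[0].covariates.keys())
        else:
            cand = list(self.candidates)
        selection = adaptive_prespecification(
            summaries, cand, scale=self.scale, matched=self.matched,
            randomization_prob=self.randomization_prob, full=True,
        )
        est = tmle_effect(
            summaries, selection.spec, scale=self.scale, matched=self.matched,
            randomization_prob=self.randomization_prob,
        )
        est = inference(est, matched=self.matched)
        return TwoStageTMLEResults(self, est, selection, stage1_fits, summaries)


class TwoStageTMLEResults:
    """Fitted Two-Stage TMLE with estimates, inference and diagnostics."""

    def __init__(
        self,
        model: TwoStageTMLE,
        estimate: EffectEstimate,
        selection: SelectionResult,
        stage1_fits: dict[object, Stage1Fit],
        summaries: list[ClusterSummary],
    ):
        self.model = model
        self.effect = estimate
        self.selection = selection
        self.stage1_fits = stage1_fits
        self.summaries = summaries

    # -- statsmodels-style accessors ------------------------------------
    @property
    def psi1(self) -> float:
        return self.effect.psi1

    @property
    def psi0(self) -> float:
        return self.effect.psi0

    @property
    def estimate(self) -> float:
        return self.effect.estimate

    @property
    def se(self) -> float:
        return self.effect.se

    @property
    def df(self) -> int:
        return self.effect.df

    @property
    def pvalue(self) -> float:
        return self.effect.p_value

    @property
    def ic(self) -> np.ndarray:
        return self.effect.ic

    @property
    def adjustment(self) -> AdjustmentSpec:
        return self.effect.selection

    def conf_int(self) -> tuple[float, float]:
        return (self.effect.ci_lo, self.effect.ci_hi)

    def endpoint_frame(self) -> pd.DataFrame:
        """Per-cluster Stage-1 endpoints and targeting diagnostics."""
        rows = []
        for s in self.summaries:
            f = self.stage1_fits[s.cluster_id]
            rows.append(
                {
                    "cluster_id": s.cluster_id,
                    "pair_id": s.pair_id,
                    "a": s.a,
                    "y_c_hat": f.y_c_hat,
                    "n_measured": f.metadata.get("n_measured"),
                    "epsilon": f.epsilon,
                    "eif_residual": f.eif_residual,
                    "g_truncated": f.n_truncated,
                }
            )
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        dm.write_results(self.effect, path)

    def summary(self) -> str:
        e = self.effect
        null = 0.0 if e.scale == "RD" else 1.0
        name = "Risk difference" if e.scale == "RD" else "Risk ratio"
        lines = [
            "Two-Stage TMLE for a cluster randomized trial",
            "=" * 53,
            f"Clusters: {len(self.summaries)}"
            + (
                f" ({len(self.summaries) // 2} matched pairs)"
                if e.matched
                else " (matches broken)"
            ),
            f"Stage 1 endpoint:  {self.model.stage1}",
            f"Stage 2 adjustment (adaptive prespecification):",
            f"  outcome regression: {e.selection.or_covariate or 'unadjusted'}",
            f"  propensity score:   {e.selection.ps_covariate or 'known (%.2g)' % e.randomization_prob}",
            "-" * 53,
            f"psi(1) = {e.psi1:.4f}   psi(0) = {e.psi0:.4f}",
            f"{name}: {e.estimate:.4f}",
            f"SE ({'log scale, ' if e.scale == 'RR' else ''}IC-based): "
            f"{e.se:.4f}   df = {e.df}",
            f"{int(e.level * 100)}% CI: ({e.ci_lo:.4f}, {e.ci_hi:.4f})",
            f"p-value (H0: {name.lower()} = {null:g}): {e.p_value:.4g}",
            "=" * 53,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        e = self.effect
        return (
            f"<TwoStageTMLEResults {e.scale}={e.estimate:.4f} "
            f"CI=({e.ci_lo:.4f}, {e.ci_hi:.4f})>"
        )
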