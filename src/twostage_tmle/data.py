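"""Domain types and text I/O for cluster randomized trial (CRT) data.

A trial is a collection of clusters; each cluster carries its randomized
arm ``a``, cluster-level baseline covariates ``e``, and one row per
participant holding baseline covariates ``w``, post-baseline covariates
``m``, the measurement indicator ``delta`` and — only when measured —
the outcome ``y``.  Unmeasured outcomes are represented by an explicit
absent state (``None`` per record, a compacted measured-only vector in
the columnar store), never by a sentinel value, so that an unmeasured
outcome can never silently enter an estimator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class IndividualRecord:
    """One participant: (w, m, delta, y) with y present iff delta == 1."""

    w: np.ndarray
    m: np.ndarray
    delta: int
    y: float | None = None

    def __post_init__(self):
        if self.delta not in (0, 1):
            raise ValidationError(f"delta must be 0 or 1, got {self.delta}")
        if self.delta == 0 and self.y is not None:
            raise ValidationError("outcome present for an unmeasured individual")
        if self.delta == 1 and self.y is None:
            raise ValidationError("outcome absent for a measured individual")


@dataclass
class ClusterData:
    """Columnar store of one cluster's individual-level data.

    ``w`` is (S, p_w), ``m`` is (S, p_m), ``delta`` is (S,) in {0,1}.
    ``y_measured`` holds outcomes for the measured individuals only, in
    row order of ``delta == 1``.
    """

    cluster_id: object
    a: int
    e: np.ndarray
    w: np.ndarray
    m: np.ndarray
    delta: np.ndarray
    y_measured: np.ndarray
    pair_id: object | None = None
    w_names: tuple[str, ...] = ()
    m_names: tuple[str, ...] = ()
    e_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.e = np.atleast_1d(np.asarray(self.e, dtype=float))
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        self.m = np.atleast_2d(np.asarray(self.m, dtype=float))
        self.delta = np.asarray(self.delta, dtype=int)
        self.y_measured = np.asarray(self.y_measured, dtype=float)
        if self.a not in (0, 1):
            raise ValidationError(
                f"cluster {self.cluster_id}: treatment must be 0/1, got {self.a}"
            )
        s = self.delta.shape[0]
        if s < 1:
            raise ValidationError(f"cluster {self.cluster_id}: empty cluster")
        if self.w.shape[0] != s or self.m.shape[0] != s:
            raise ValidationError(
                f"cluster {self.cluster_id}: covariate rows do not match delta length"
            )
        if not np.isin(self.delta, (0, 1)).all():
            raise ValidationError(f"cluster {self.cluster_id}: delta must be 0/1")
        if self.y_measured.shape[0] != int(self.delta.sum()):
            raise ValidationError(
                f"cluster {self.cluster_id}: {self.y_measured.shape[0]} outcomes "
                f"for {int(self.delta.sum())} measured individuals"
            )
        if not self.w_names:
            self.w_names = tuple(f"w{i + 1}" for i in range(self.w.shape[1]))
        if not self.m_names:
            self.m_names = tuple(f"m{i + 1}" for i in range(self.m.shape[1]))
        if not self.e_names:
            self.e_names = tuple(f"e{i + 1}c" for i in range(self.e.shape[0]))

    @property
    def size(self) -> int:
        return self.delta.shape[0]

    @property
    def n_measured(self) -> int:
        return int(self.delta.sum())

    @property
    def individuals(self) -> Iterator[IndividualRecord]:
        ys = iter(self.y_measured)
        for j in range(self.size):
            d = int(self.delta[j])
            yield IndividualRecord(
                w=self.w[j], m=self.m[j], delta=d, y=float(next(ys)) if d else None
            )

    def covariate_matrix(self) -> np.ndarray:
        """(S, p_w + p_m) design of baseline and post-baseline covariates."""
        return np.column_stack([self.w, self.m])


@dataclass
class ClusterSummary:
    """Cluster-level record O^c = (e, w_summary, a, y_c_hat) for Stage 2."""

    cluster_id: object
    a: int
    y_c_hat: float
    e: dict[str, float] = field(default_factory=dict)
    w_summary: dict[str, float] = field(default_factory=dict)
    pair_id: object | None = None

    def __post_init__(self):
        if self.a not in (0, 1):
            raise ValidationError(
                f"cluster {self.cluster_id}: treatment must be 0/1, got {self.a}"
            )
        if not math.isfinite(self.y_c_hat):
            raise ValidationError(f"cluster {self.cluster_id}: non-finite endpoint")

    @property
    def covariates(self) -> dict[str, float]:
        """Merged cluster-level adjustment covariates (e then w summaries)."""
        merged = dict(self.e)
        merged.update(self.w_summary)
        return merged


@dataclass
class Trial:
    """A CRT: clusters plus a flag for whether pair-matching is in force."""

    clusters: list
    matched: bool = False

    def __post_init__(self):
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate cluster ids")
        if self.matched:
            pairs: dict[object, list[int]] = {}
            for c in self.clusters:
                if c.pair_id is None:
                    raise ValidationError(
                        f"cluster {c.cluster_id}: matched trial requires pair ids"
                    )
                pairs.setdefault(c.pair_id, []).append(c.a)
            for pid, arms in pairs.items():
                if sorted(arms) != [0, 1]:
                    raise ValidationError(
                        f"pair {pid} must contain exactly one treated and one "
                        f"control cluster, got arms {arms}"
                    )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def arms(self) -> np.ndarray:
        return np.array([c.a for c in self.clusters], dtype=int)


DEFAULT_SCHEMA: dict[str, object] = {
    "cluster_id": "cluster_id",
    "pair_id": "pair_id",
    "a": "a",
    "delta": "delta",
    "y": "y",
    # None means: infer by prefix from remaining columns
    "e_cols": None,
    "w_cols": None,
    "m_cols": None,
}


def _resolve_schema(columns: Sequence[str], schema: Mapping | None):
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    fixed = {sch["cluster_id"], sch["a"], sch["delta"], sch["y"], sch["pair_id"]}
    rest = [c for c in columns if c not in fixed]
    for role, prefix in (("e_cols", "e"), ("w_cols", "w"), ("m_cols", "m")):
        if sch[role] is None:
            sch[role] = [c for c in rest if c.startswith(prefix)]
    return sch


def read_trial(path, schema: Mapping | None = None, matched: bool | None = None) -> Trial:
    """Read an individual-level trial from a delimited text file.

    One row per participant.  Cluster-constant columns (arm, pair id,
    cluster-level covariates) must be identical within each cluster id;
    the outcome cell must be empty exactly when ``delta`` is 0.  When
    ``matched`` is None the pair structure is used iff a pair-id column
    with non-missing values is present.
    """
    df = pd.read_csv(path)
    return trial_from_dataframe(df, schema=schema, matched=matched)


def trial_from_dataframe(
    df: pd.DataFrame, schema: Mapping | None = None, matched: bool | None = None
) -> Trial:
    sch = _resolve_schema(df.columns, schema)
    cid, acol, dcol, ycol = sch["cluster_id"], sch["a"], sch["delta"], sch["y"]
    pcol = sch["pair_id"]
    have_pairs = pcol in df.columns and df[pcol].notna().all()
    if matched is None:
        matched = bool(have_pairs)
    if matched and not have_pairs:
        raise ValidationError("matched analysis requested but pair ids are missing")

    clusters = []
    for gid, g in df.groupby(cid, sort=False):
        const_cols = [acol] + list(sch["e_cols"]) + ([pcol] if have_pairs else [])
        for col in const_cols:
            if g[col].nunique(dropna=False) != 1:
                raise ValidationError(
                    f"cluster {gid}: column {col!r} is not constant within cluster"
                )
        delta = g[dcol].to_numpy(dtype=int)
        yvals = g[ycol]
        if yvals.notna().to_numpy().astype(int).tolist() != delta.tolist():
            bad = "present" if (yvals.notna() & (g[dcol] == 0)).any() else "missing"
            raise ValidationError(
                f"cluster {gid}: outcome {bad} inconsistent with delta"
            )
        clusters.append(
            ClusterData(
                cluster_id=gid,
                pair_id=g[pcol].iloc[0] if have_pairs else None,
                a=int(g[acol].iloc[0]),
                e=g[list(sch["e_cols"])].iloc[0].to_numpy(dtype=float),
                w=g[list(sch["w_cols"])].to_numpy(dtype=float),
                m=g[list(sch["m_cols"])].to_numpy(dtype=float),
                delta=delta,
                y_measured=yvals[g[dcol] == 1].to_numpy(dtype=float),
                w_names=tuple(sch["w_cols"]),
                m_names=tuple(sch["m_cols"]),
                e_names=tuple(sch["e_cols"]),
            )
        )
    return Trial(clusters=clusters, matched=matched)


def trial_to_dataframe(trial: Trial) -> pd.DataFrame:
    rows = []
    for c in trial.clusters:
        ys = np.full(c.size, np.nan)
        ys[c.delta == 1] = c.y_measured
        for j in range(c.size):
            row = {"cluster_id": c.cluster_id, "a": c.a}
            if c.pair_id is not None:
                row["pair_id"] = c.pair_id
            row.update({n: c.e[k] for k, n in enumerate(c.e_names)})
            row.update({n: c.w[j, k] for k, n in enumerate(c.w_names)})
            row.update({n: c.m[j, k] for k, n in enumerate(c.m_names)})
            row["delta"] = int(c.delta[j])
            row["y"] = ys[j]
            rows.append(row)
    return pd.DataFrame(rows)


def write_trial(trial: Trial, path) -> None:
    """Write a trial as individual-level CSV (readable by read_trial)."""
    trial_to_dataframe(trial).to_csv(path, index=False, float_format="%.12g")


def summarize_cluster(
    cluster: ClusterData,
    y_c_hat: float,
    w_aggregators: Mapping[str, Callable[[np.ndarray], float]] | None = None,
) -> ClusterSummary:
    """Collapse a cluster to its Stage-2 record.

    ``w_aggregators`` maps individual-level baseline covariate names to
    scalar aggregation functions; the default summarizes every ``w``
    column by its within-cluster mean.
    """
    if cluster.size < 1:
        raise ValidationError("empty cluster cannot be summarized")
    if w_aggregators is None:
        w_aggregators = {name: np.mean for name in cluster.w_names}
    w_summary = {}
    for name, fn in w_aggregators.items():
        if name not in cluster.w_names:
            raise ValidationError(f"unknown baseline covariate {name!r}")
        col = cluster.w[:, cluster.w_names.index(name)]
        w_summary[f"{name}c"] = float(fn(col))
    e = {n: float(v) for n, v in zip(cluster.e_names, cluster.e)}
    return ClusterSummary(
        cluster_id=cluster.cluster_id,
        pair_id=cluster.pair_id,
        a=cluster.a,
        e=e,
        w_summary=w_summary,
        y_c_hat=float(y_c_hat),
    )


def read_summaries(path) -> list[ClusterSummary]:
    """Read a cluster-summary CSV (cluster_id, [pair_id], a, e*/w*, y_c_hat)."""
    df = pd.read_csv(path)
    have_pairs = "pair_id" in df.columns and df["pair_id"].notna().all()
    reserved = {"cluster_id", "pair_id", "a", "y_c_hat"}
    cov_cols = [c for c in df.columns if c not in reserved]
    out = []
    for _, row in df.iterrows():
        covs = {c: float(row[c]) for c in cov_cols}
        out.append(
            ClusterSummary(
                cluster_id=row["cluster_id"],
                pair_id=row["pair_id"] if have_pairs else None,
                a=int(row["a"]),
                e={k: v for k, v in covs.items() if k.startswith("e")},
                w_summary={k: v for k, v in covs.items() if not k.startswith("e")},
                y_c_hat=float(row["y_c_hat"]),
            )
        )
    return out


def write_summaries(summaries: Sequence[ClusterSummary], path) -> None:
    rows = []
    for s in summaries:
        row = {"cluster_id": s.cluster_id, "a": s.a}
        if s.pair_id is not None:
            row["pair_id"] = s.pair_id
        row.update(s.covariates)
        row["y_c_hat"] = s.y_c_hat
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


_RESULT_FIELDS = (
    "psi1",
    "psi0",
    "scale",
    "estimate",
    "se",
    "df",
    "ci_lo",
    "ci_hi",
    "p_value",
    "matched",
)


def write_results(estimate, path) -> None:
    """Write an effect estimate as JSON key-value text.

    Requires a complete estimate (inference already attached); numeric
    fields round-trip at 12 significant digits.
    """
    payload = {}
    for name in _RESULT_FIELDS:
        value = getattr(estimate, name, None)
        if value is None:
            raise ValidationError(f"incomplete estimate: missing {name!r}")
        payload[name] = value
    payload["ic"] = [float(f"{v:.12g}") for v in np.asarray(estimate.ic, dtype=float)]
    sel = getattr(estimate, "selection", None)
    payload["selection"] = {
        "or_covariate": getattr(sel, "or_covariate", None),
        "ps_covariate": getattr(sel, "ps_covariate", None),
    }
    for name in ("psi1", "psi0", "estimate", "se", "ci_lo", "ci_hi", "p_value"):
        payload[name] = float(f"{payload[name]:.12g}")
    payload["df"] = int(payload["df"])
    payload["matched"] = bool(payload["matched"])
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
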