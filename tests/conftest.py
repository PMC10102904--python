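import numpy as np
import pytest

from twostage_tmle.data import ClusterData, ClusterSummary, Trial


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_cluster(
    rng,
    cluster_id=0,
    a=1,
    size=40,
    pair_id=None,
    p_measure=0.7,
    e=(0.1, -0.2),
):
    """A random well-formed cluster with at least one measured outcome."""
    w = rng.normal(size=(size, 2))
    m = rng.integers(0, 2, size=(size, 1)).astype(float)
    delta = (rng.uniform(size=size) < p_measure).astype(int)
    if delta.sum() == 0:
        delta[0] = 1
    y = rng.integers(0, 2, size=int(delta.sum())).astype(float)
    return ClusterData(
        cluster_id=cluster_id,
        pair_id=pair_id,
        a=a,
        e=np.asarray(e, dtype=float),
        w=w,
        m=m,
        delta=delta,
        y_measured=y,
    )


def make_summaries(rng, n=10, matched=False, y_fn=None):
    """Random cluster summaries with n/2 clusters per arm."""
    out = []
    for i in range(n):
        a = i % 2
        e1, e2 = rng.normal(), rng.normal()
        if y_fn is None:
            y = float(np.clip(0.5 + 0.1 * a + 0.1 * rng.normal(), 0.01, 0.99))
        else:
            y = y_fn(a, e1, e2)
        out.append(
            ClusterSummary(
                cluster_id=i,
                pair_id=i // 2 if matched else None,
                a=a,
                e={"e1c": e1, "e2c": e2},
                w_summary={"w1c": float(rng.normal())},
                y_c_hat=y,
            )
        )
    return out


@pytest.fixture
def small_trial(rng):
    clusters = [
        make_cluster(rng, cluster_id=i, a=i % 2, pair_id=i // 2, size=30)
        for i in range(8)
    ]
    return Trial(clusters=clusters, matched=True)
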