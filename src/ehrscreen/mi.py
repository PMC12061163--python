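"""Mutual information between feature sets and caseness, scaled and ranked.

Binary and low-cardinality count features use the exact plug-in estimator
on the empirical joint frequency table. Continuous (and high-cardinality
count) features use the nearest-neighbour estimator for mixed
discrete-continuous pairs (Ross 2014): for each point, find the distance
to its k-th nearest neighbour *within its own class*, count the
neighbours of the full sample inside that radius, and combine digamma
terms; a tiny symmetric jitter breaks ties, so the estimate is averaged
over ``n_runs`` randomisations (the reported value is the arithmetic mean
of the runs).

All mutual information is in nats and is scaled to the entropy of the
caseness variable for reporting ("scaled MI", as a percentage).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma

DISCRETE_CARDINALITY_LIMIT = 30  # count features beyond this go to the k-NN path


def binary_entropy(p: float) -> float:
    """Entropy of a Bernoulli(p) variable in nats, with 0 ln 0 = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log(p) - (1 - p) * np.log(1 - p))


def plugin_mi_discrete(x: np.ndarray, y: np.ndarray) -> float:
    """Exact plug-in MI (nats) from the empirical joint frequency table."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    return _mi_of_table(joint)


def _mi_of_table(joint: np.ndarray) -> float:
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = joint * np.log(joint / (px * py))
    return float(np.nansum(t))


def plugin_mi_binary_many(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plug-in MI of many 0/1 columns against a 0/1 target, vectorised."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    n11 = X.T @ y
    n1x = X.sum(axis=0)
    ny1 = y.sum()
    cells = np.stack(
        [n - n1x - ny1 + n11, ny1 - n11, n1x - n11, n11], axis=1
    )  # (K, 4): (0,0),(0,1),(1,0),(1,1)
    p = cells / n
    px = np.stack([p[:, 0] + p[:, 1], p[:, 2] + p[:, 3]], axis=1)
    py = np.stack([p[:, 0] + p[:, 2], p[:, 1] + p[:, 3]], axis=1)
    prod = np.stack(
        [px[:, 0] * py[:, 0], px[:, 0] * py[:, 1], px[:, 1] * py[:, 0], px[:, 1] * py[:, 1]],
        axis=1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log(p / prod)
    return np.nansum(t, axis=1)


class EstimatorSkipped(RuntimeError):
    """A class had too few points for the k-NN estimator."""


def _ross_mi_once(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """One evaluation of the Ross discrete-continuous estimator (1-D x)."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    d = np.empty(n)
    n_class = np.empty(n)
    for cls in np.unique(ys):
        pos = np.flatnonzero(ys == cls)
        arr = xs[pos]
        nc = len(arr)
        if nc <= k:
            raise EstimatorSkipped(f"class {cls!r} has {nc} <= k={k} points")
        pad = np.concatenate([np.full(k, -np.inf), arr, np.full(k, np.inf)])
        win = np.lib.stride_tricks.sliding_window_view(pad, 2 * k + 1)
        dist = np.abs(win - arr[:, None])
        dist.sort(axis=1)
        d[pos] = dist[:, k]  # k-th nearest within class (self at rank 0)
        n_class[pos] = nc
    hi = np.searchsorted(xs, xs + d, side="left")
    lo = np.searchsorted(xs, xs - d, side="right")
    m = hi - lo  # strictly inside the radius, self included
    return float(digamma(n) - np.mean(digamma(n_class)) + digamma(k) - np.mean(digamma(m)))


@dataclass
class MIEstimate:
    feature_id: str
    mi_nats: float
    mi_scaled: float
    estimator: str                       # plugin_discrete | knn_mixed
    n_runs: int = 1
    n_used: int = 0
    runs: tuple[float, ...] = field(default_factory=tuple)


def knn_mixed_mi(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    n_runs: int = 20,
    seed: int | np.random.SeedSequence = 0,
    feature_id: str = "",
    caseness_entropy: float | None = None,
) -> MIEstimate:
    """Mean of ``n_runs`` jittered evaluations of the Ross k-NN estimator.

    The jitter is symmetric noise at 1e-10 of the interquartile range
    (falling back to the standard deviation, then to 1) — just enough to
    break ties — seeded per run from ``seed``. The mean is clamped at zero
    before scaling; per-run raw values are retained.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    scale = np.subtract(*np.percentile(x, [75, 25]))
    if scale <= 0:
        scale = x.std() or 1.0
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    runs = []
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        xj = x + rng.standard_normal(x.shape) * (1e-10 * scale)
        runs.append(_ross_mi_once(xj, y, k))
    mean = max(float(np.mean(runs)), 0.0)
    h = caseness_entropy
    return MIEstimate(
        feature_id=feature_id,
        mi_nats=mean,
        mi_scaled=mean / h if h else np.nan,
        estimator="knn_mixed",
        n_runs=n_runs,
        n_used=len(x),
        runs=tuple(runs),
    )


def rank_feature_sets(estimates: list[MIEstimate]) -> pd.DataFrame:
    """Sort by scaled MI descending, ties broken by feature_id.

    Returns a table with 1-based ranks; the caller is expected to have
    excluded non-informative (single-valued) feature sets already.
    """
    if not estimates:
        return pd.DataFrame(
            columns=["feature_id", "estimator", "mi_nats", "mi_scaled", "n_used", "rank"]
        )
    df = pd.DataFrame(
        {
            "feature_id": [e.feature_id for e in estimates],
            "estimator": [e.estimator for e in estimates],
            "mi_nats": [e.mi_nats for e in estimates],
            "mi_scaled": [e.mi_scaled for e in estimates],
            "n_used": [e.n_used for e in estimates],
        }
    )
    df = df.sort_values(
        ["mi_scaled", "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
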