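"""Entropy measures of appointment and non-attendance series.

All measures work on monthly-binned series. Normalised entropies lie in
[0, 1]; sample entropy and active information are non-negative; a missing
value (``nan``) means the series was too short, constant, or otherwise
outside the measure's domain. Logarithms are natural throughout.

Each measure has a batch form operating on a ``(n_series, n_months)``
matrix — the extraction pipeline feeds tens of thousands of patients at
once — and the scalar form is the batch form on a single row.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "sample_entropy",
    "sample_entropy_batch",
    "spectral_entropy",
    "spectral_entropy_batch",
    "average_quarterly_entropy",
    "average_quarterly_entropy_batch",
    "active_information",
    "active_information_batch",
]


def sample_entropy_batch(
    X: np.ndarray, m: int = 2, r: np.ndarray | float | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Sample entropy of each row of ``X``.

    ``-ln(A/B)`` with ``B`` (resp. ``A``) the number of template pairs of
    length ``m`` (resp. ``m + 1``) within Chebyshev distance ``r``,
    self-matches excluded. ``r`` defaults to ``0.2 * SD`` per row; rows
    where ``r`` resolves to zero, or where no template pair matches,
    yield ``nan``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_series, n_months)")
    n_series, T = X.shape
    out = np.full(n_series, np.nan)
    if T < m + 2:
        return out
    if r is None:
        r_vec = 0.2 * X.std(axis=1)
    else:
        r_vec = np.broadcast_to(np.asarray(r, dtype=float), (n_series,)).copy()
    nt = T - m  # templates usable at both lengths
    iu = np.triu_indices(nt, k=1)
    for lo in range(0, n_series, chunk):
        xs = X[lo:lo + chunk]
        d0 = np.abs(xs[:, :, None] - xs[:, None, :])
        Dm = d0[:, :nt, :nt].copy()
        for o in range(1, m):
            np.maximum(Dm, d0[:, o:o + nt, o:o + nt], out=Dm)
        Dm1 = np.maximum(Dm, d0[:, m:m + nt, m:m + nt])
        rr = r_vec[lo:lo + chunk, None]
        B = (Dm[:, iu[0], iu[1]] <= rr).sum(axis=1)
        A = (Dm1[:, iu[0], iu[1]] <= rr).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = -np.log(A / B)
        v[(B == 0) | (A == 0)] = np.nan
        v[r_vec[lo:lo + chunk] <= 0] = np.nan
        out[lo:lo + chunk] = v
    return out


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy of a single monthly series (see batch form)."""
    return float(sample_entropy_batch(np.asarray(x, float)[None, :], m=m, r=r)[0])


def spectral_entropy_batch(X: np.ndarray, min_months: int = 24) -> np.ndarray:
    """Normalised spectral entropy of each row's mean-centred series.

    Shannon entropy of the power spectrum over positive frequencies,
    normalised by the log of the number of spectral bins. Constant rows
    (zero total power) and series shorter than ``min_months`` are missing.
    """
    X = np.asarray(X, dtype=float)
    n_series, T = X.shape
    out = np.full(n_series, np.nan)
    if T < min_months:
        return out
    xc = X - X.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(xc, axis=1)[:, 1:]) ** 2  # positive frequencies
    tot = spec.sum(axis=1, keepdims=True)
    nbins = spec.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = spec / tot
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1) / np.log(nbins)
    h[tot[:, 0] <= 0] = np.nan
    return h


def spectral_entropy(x: np.ndarray, min_months: int = 24) -> float:
    return float(spectral_entropy_batch(np.asarray(x, float)[None, :], min_months)[0])


def quarterly_entropy_per_year(Q: np.ndarray) -> np.ndarray:
    """Normalised entropy of each year's quarterly proportions.

    ``Q`` has shape ``(n_series, n_years, 4)``; returns ``(n_series,
    n_years)``. An all-zero year scores 0 (perfectly unsurprising).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 3 or Q.shape[2] != 4:
        raise ValueError("Q must have shape (n_series, n_years, 4)")
    tot = Q.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = Q / tot
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=2) / np.log(4.0)
    return np.where(tot[:, :, 0] > 0, h, 0.0)


def average_quarterly_entropy_batch(Q: np.ndarray) -> np.ndarray:
    """Mean normalised entropy of quarterly non-attendance, per series.

    ``Q`` has shape ``(n_series, n_years, 4)`` of quarterly DNA counts over
    full calendar years. Each year contributes the Shannon entropy of its
    quarterly proportions normalised by ``ln 4``; an all-zero year
    contributes 0. A series with no full year is missing.
    """
    Q = np.asarray(Q, dtype=float)
    n_series = Q.shape[0]
    if Q.shape[1] == 0:
        return np.full(n_series, np.nan)
    return quarterly_entropy_per_year(Q).mean(axis=1)


def average_quarterly_entropy(quarterly: np.ndarray) -> float:
    """Scalar form; ``quarterly`` has shape (n_years, 4)."""
    q = np.asarray(quarterly, dtype=float)
    return float(average_quarterly_entropy_batch(q[None, :, :])[0])


def active_information_batch(
    B: np.ndarray, history_months: int = 12, recent_months: int = 3
) -> np.ndarray:
    """Active information of each row's binarised non-attendance indicator.

    Plug-in mutual information (nats) between the ``recent_months``-month
    history pattern and the following month's indicator, pooled over the
    ``history_months`` sliding windows inside the final
    ``history_months + recent_months`` months. Zero when the indicator is
    constant; missing when the series is too short.
    """
    B = np.asarray(B)
    n_series, T = B.shape
    W = history_months + recent_months
    out = np.full(n_series, np.nan)
    if T < W or history_months < 1 or recent_months < 1:
        return out
    b = (B[:, T - W:] > 0).astype(np.int64)
    npat = 2 ** recent_months
    # pattern id and next-month bit for each sliding window
    pats = np.zeros((n_series, history_months), dtype=np.int64)
    for o in range(recent_months):
        pats = pats * 2 + b[:, o:o + history_months]
    nxt = b[:, recent_months:recent_months + history_months]
    cell = pats * 2 + nxt
    counts = np.zeros((n_series, npat * 2), dtype=np.int64)
    rows = np.repeat(np.arange(n_series), history_months)
    np.add.at(counts, (rows, cell.ravel()), 1)
    joint = counts.reshape(n_series, npat, 2) / history_months
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = joint * np.log(joint / (px * py))
    return np.maximum(np.nansum(t, axis=(1, 2)), 0.0)


def active_information(
    b: np.ndarray, history_months: int = 12, recent_months: int = 3
) -> float:
    return float(
        active_information_batch(np.asarray(b)[None, :], history_months, recent_months)[0]
    )
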