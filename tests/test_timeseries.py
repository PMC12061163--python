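"""Entropy measures against brute-force oracles and analytic limits."""
import itertools
import math

import numpy as np
import pytest

from ehrscreen.timeseries import (
    active_information,
    average_quarterly_entropy,
    sample_entropy,
    spectral_entropy,
)


# ---------------------------------------------------------------- oracles --
def sampen_oracle(x, m=2, r=None):
    """O(n^2) template-matching sample entropy, straight from the definition."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0 or n < m + 2:
        return math.nan
    nt = n - m
    B = A = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + o] - x[j + o]) for o in range(m)) <= r:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    if B == 0 or A == 0:
        return math.nan
    return -math.log(A / B)


def quarterly_oracle(Q):
    """Per-year Shannon entropy of quarterly proportions, averaged."""
    hs = []
    for year in np.asarray(Q, float):
        tot = year.sum()
        if tot == 0:
            hs.append(0.0)
            continue
        p = year / tot
        hs.append(-sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(4))
    return float(np.mean(hs)) if hs else math.nan


def active_info_oracle(b, history=12, recent=3):
    """Plug-in MI from the exact pattern-frequency table of the windows."""
    b = (np.asarray(b)[-(history + recent):] > 0).astype(int)
    pairs = [(tuple(b[t - recent:t]), b[t]) for t in range(recent, recent + history)]
    n = len(pairs)
    from collections import Counter

    joint = Counter(pairs)
    px = Counter(p for p, _ in pairs)
    py = Counter(v for _, v in pairs)
    mi = sum(
        (c / n) * math.log((c / n) / ((px[p] / n) * (py[v] / n)))
        for (p, v), c in joint.items()
    )
    return max(mi, 0.0)


# ---------------------------------------------------------- sample entropy --
def test_sample_entropy_constant_series_is_zero_with_explicit_tolerance():
    assert sample_entropy(np.full(30, 5.0), r=0.5) == 0.0


def test_sample_entropy_constant_series_default_tolerance_is_missing():
    assert math.isnan(sample_entropy(np.full(30, 5.0)))


def test_sample_entropy_alternating_series_matches_oracle():
    x = np.tile([0.0, 1.0], 15)
    assert sample_entropy(x) == pytest.approx(sampen_oracle(x), abs=1e-12)


def test_sample_entropy_translation_invariant():
    rng = np.random.default_rng(1)
    x = rng.poisson(2.0, 40).astype(float)
    r = 0.2 * x.std()
    assert sample_entropy(x, r=r) == pytest.approx(sample_entropy(x + 7.0, r=r), abs=1e-12)


def test_sample_entropy_random_series_match_oracle():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(8, 30))
        x = rng.poisson(1.5, n).astype(float)
        got = sample_entropy(x)
        want = sampen_oracle(x)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


# -------------------------------------------------------- spectral entropy --
def test_spectral_entropy_pure_periodic_is_near_zero():
    t = np.arange(48)
    x = 1.0 + np.cos(2 * np.pi * t / 12)  # an exact DFT bin: one spectral line
    assert spectral_entropy(x) == pytest.approx(0.0, abs=1e-10)


def test_spectral_entropy_white_noise_expectation_near_one():
    """iid months: flat expected spectrum, entropy near its plug-in ceiling.

    Periodogram powers of white noise are ~iid exponential, so the expected
    plug-in entropy is ln(n_bins) - (1 - gamma); the normalised measure
    should concentrate near that ceiling, just below 1.
    """
    rng = np.random.default_rng(3)
    vals = [spectral_entropy(rng.integers(0, 2, 48).astype(float)) for _ in range(200)]
    n_bins = 48 // 2  # positive-frequency bins of a length-48 series
    expected = 1.0 - (1.0 - np.euler_gamma) / np.log(n_bins)
    assert np.nanmean(vals) == pytest.approx(expected, abs=0.02)
    assert np.nanmean(vals) > 0.8


def test_spectral_entropy_bounds_and_degenerate_inputs():
    rng = np.random.default_rng(4)
    for _ in range(100):
        x = rng.poisson(1.0, int(rng.integers(24, 60))).astype(float)
        v = spectral_entropy(x)
        if not math.isnan(v):
            assert 0.0 <= v <= 1.0
    assert math.isnan(spectral_entropy(np.full(48, 2.0)))   # constant: no power
    assert math.isnan(spectral_entropy(np.ones(12)))        # too short


# ------------------------------------------------------- quarterly entropy --
def test_quarterly_entropy_point_mass_is_zero():
    q = np.zeros((3, 4))
    q[:, 2] = 5
    assert average_quarterly_entropy(q) == 0.0


def test_quarterly_entropy_uniform_is_one():
    q = np.full((2, 4), 3.0)
    assert average_quarterly_entropy(q) == pytest.approx(1.0, abs=1e-12)


def test_quarterly_entropy_mixed_years_match_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        q = rng.poisson(1.2, size=(int(rng.integers(1, 5)), 4))
        assert average_quarterly_entropy(q) == pytest.approx(quarterly_oracle(q), abs=1e-12)


# ------------------------------------------------------- active information --
def test_active_information_constant_indicator_is_zero():
    assert active_information(np.zeros(20)) == 0.0
    assert active_information(np.ones(20)) == 0.0


def test_active_information_periodic_pattern_matches_exact_table():
    for period in (2, 3):
        b = np.tile(np.r_[np.ones(1), np.zeros(period - 1)], 10)[:20]
        got = active_information(b)
        assert got == pytest.approx(active_info_oracle(b), abs=1e-12)
        assert got > 0.1  # a periodic pattern is predictable from its past


def test_active_information_random_series_match_oracle():
    rng = np.random.default_rng(6)
    for _ in range(100):
        b = rng.integers(0, 2, int(rng.integers(15, 40)))
        assert active_information(b) == pytest.approx(active_info_oracle(b), abs=1e-12)


def test_active_information_independent_months_bounded_by_permutation_null():
    """Small-sample bias on iid months stays inside the permutation null."""
    rng = np.random.default_rng(7)
    obs = np.mean([active_information(rng.random(15) < 0.4) for _ in range(200)])
    null = []
    for _ in range(200):
        b = (rng.random(15) < 0.4).astype(int)
        rng.shuffle(b)
        null.append(active_information(b))
    assert obs <= np.quantile(null, 0.99) + 0.05


def test_active_information_too_short_is_missing():
    assert math.isnan(active_information(np.ones(10)))
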