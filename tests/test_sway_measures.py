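"""Basic and nonlinear sway measures against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swayabc import (
    EmbeddingSpec,
    FseParams,
    basic_measures,
    compare_measures,
    correlation_dimension,
    dfa_alpha,
    fuzzy_sample_entropy,
    largest_lyapunov,
    mutual_information_lag,
)

FS = 50.0


class TestBasicMeasures:
    def test_constant_signal(self):
        m = basic_measures([1.0, 1.0, 1.0], FS)
        assert (m.MD, m.MV, m.MA, m.MF) == (1.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        m = basic_measures([0.0, 1.0, 0.0], FS)
        assert m.MD == pytest.approx(1 / 3)
        assert m.MV == pytest.approx(50.0)
        assert m.MA == pytest.approx(5000.0)
        assert m.MF == pytest.approx(50.0 / (2 * math.pi / 3))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_frequency_identity(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        m = basic_measures(x, FS)
        assert m.MF * 2 * math.pi * m.MD == pytest.approx(m.MV, rel=1e-12)

    def test_sign_flip_invariance(self, rng):
        x = rng.normal(size=500)
        a, b = basic_measures(x, FS), basic_measures(-x, FS)
        assert (a.MD, a.MV, a.MA, a.MF) == pytest.approx((b.MD, b.MV, b.MA, b.MF))

    def test_too_short(self):
        with pytest.raises(ValueError):
            basic_measures([1.0, 2.0], FS)


def brute_force_fse(x, L, r_tol, c_shape):
    """Independent O(n^2 L) double-loop reference implementation."""
    x = np.asarray(x, float)
    sd = x.std()
    if sd > 0:
        x = x / sd
    q = math.log(c_shape * math.log(2.0)) / math.log(r_tol)

    def mu(d):
        return 1.0 if d == 0.0 else math.exp(-(d ** q) / c_shape)

    n = len(x)
    nt = n - L
    A = B = 0.0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            dL = max(abs(x[j + k] - x[i + k]) for k in range(L))
            d1 = max(dL, abs(x[j + L] - x[i + L]))
            B += mu(dL)
            A += mu(d1)
    return -math.log(A / B)


class TestFuzzySampleEntropy:
    def test_constant_signal_is_zero(self):
        assert fuzzy_sample_entropy(np.zeros(50), FseParams(L=2)) == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=40)
        p = FseParams(L=2)
        ours = fuzzy_sample_entropy(x, p)
        ref = brute_force_fse(x, p.L, p.r_tol, p.c_shape)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_oracle_default_length(self, rng):
        x = rng.normal(size=60)
        p = FseParams()  # L = 6
        assert fuzzy_sample_entropy(x, p) == pytest.approx(
            brute_force_fse(x, p.L, p.r_tol, p.c_shape), abs=1e-12)

    def test_noise_less_predictable_than_sinusoid(self, rng):
        t = np.arange(1000) / FS
        sine = np.sin(2 * np.pi * 0.5 * t)
        noise = rng.normal(size=1000)
        noise *= sine.std() / noise.std()
        assert fuzzy_sample_entropy(noise) > fuzzy_sample_entropy(sine)

    def test_time_reversal_invariance(self, rng):
        x = rng.normal(size=300)
        assert fuzzy_sample_entropy(x) == pytest.approx(
            fuzzy_sample_entropy(x[::-1]), rel=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            fuzzy_sample_entropy(np.ones(10), FseParams(L=6))


class TestDfa:
    def test_white_noise_exponent(self):
        x = np.random.default_rng(10).normal(size=2 ** 14)
        assert dfa_alpha(x) == pytest.approx(0.5, abs=0.05)

    def test_brownian_exponent(self):
        x = np.cumsum(np.random.default_rng(11).normal(size=2 ** 14))
        assert dfa_alpha(x) == pytest.approx(1.5, abs=0.1)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=4096)
        assert dfa_alpha(1000.0 * x) == pytest.approx(dfa_alpha(x), rel=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            dfa_alpha(np.ones(8))


class TestMutualInformationLag:
    def test_sinusoid_quarter_period(self):
        # light observation noise keeps the histogram MI estimator
        # well-behaved without moving the quarter-period minimum
        t = np.arange(4000)
        x = (np.sin(2 * np.pi * t / 100.0)
             + 0.05 * np.random.default_rng(0).normal(size=4000))
        J = mutual_information_lag(x, max_lag=80)
        assert 15 <= J <= 35  # near T/4 = 25

    def test_iid_noise_immediate_minimum(self):
        x = np.random.default_rng(3).normal(size=5000)
        assert mutual_information_lag(x, max_lag=40) <= 3


class TestCorrelationDimension:
    def test_sinusoid_limit_cycle(self):
        # period incommensurate with the sampling grid, so the orbit
        # fills the closed curve instead of revisiting identical points
        t = np.arange(4000)
        x = np.sin(2 * np.pi * t / 97.3)
        d2, M, J = correlation_dimension(x)
        assert d2 == pytest.approx(1.0, abs=0.15)
        assert M > 2 * d2 + 1

    def test_two_torus(self):
        t = np.arange(6000)
        x = np.sin(2 * np.pi * t / 100.0) + np.sin(2 * t / 17.0)
        d2, _, _ = correlation_dimension(x)
        assert d2 == pytest.approx(2.0, abs=0.3)

    def test_time_reversal_invariance(self):
        t = np.arange(3000)
        x = np.sin(2 * np.pi * t / 90.0) + 0.05 * np.random.default_rng(5).normal(
            size=3000)
        d2_f, _, _ = correlation_dimension(x, J=20)
        d2_r, _, _ = correlation_dimension(x[::-1], J=20)
        assert d2_f == pytest.approx(d2_r, abs=0.1)


class TestLargestLyapunov:
    def _sine(self, n=3000, T=100.0):
        return np.sin(2 * np.pi * np.arange(n) / T)

    def test_periodic_signal_no_divergence(self):
        x = self._sine()
        lam = largest_lyapunov(x, EmbeddingSpec(J=25, M=3))
        assert abs(lam) < 0.05  # per-sample units

    def test_noise_increases_divergence(self):
        x = self._sine()
        noisy = x + 0.1 * np.random.default_rng(7).normal(size=len(x))
        lam_clean = largest_lyapunov(x, EmbeddingSpec(J=25, M=3))
        lam_noisy = largest_lyapunov(noisy, EmbeddingSpec(J=25, M=3))
        assert lam_noisy > lam_clean

    def test_amplitude_invariance(self):
        x = self._sine() + 0.05 * np.random.default_rng(8).normal(size=3000)
        a = largest_lyapunov(x, EmbeddingSpec(J=25, M=3))
        b = largest_lyapunov(2.0 * x, EmbeddingSpec(J=25, M=3))
        assert a == pytest.approx(b, abs=0.02)

    def test_per_second_scaling(self):
        x = self._sine() + 0.05 * np.random.default_rng(9).normal(size=3000)
        per_sample = largest_lyapunov(x, EmbeddingSpec(J=25, M=3))
        per_second = largest_lyapunov(x, EmbeddingSpec(J=25, M=3), fs=FS)
        assert per_second == pytest.approx(per_sample * FS, rel=1e-12)


class TestCompareMeasures:
    def _table(self, rng, shift=0.0):
        base = rng.normal(size=(10, 3)) + np.array([5.0, 2.0, 9.0])
        cols = ["MD_mm", "MV_mm_s", "MA_mm_s2"]
        return (pd.DataFrame(base, columns=cols),
                pd.DataFrame(base + shift, columns=cols))

    def test_identical_groups_flagged_nan(self, rng):
        a, b = self._table(rng, shift=0.0)
        out = compare_measures(a, b)
        assert out["p_value"].isna().all()
        assert not out["significant"].any()

    def test_large_shift_detected(self, rng):
        a, b = self._table(rng, shift=50.0)
        out = compare_measures(a, b)
        assert (out["p_value"] < 0.05).all()
        assert out["significant"].all()

    def test_schema_eight_measures(self, rng):
        cols = ["MD_mm", "MV_mm_s", "MA_mm_s2", "MF_Hz", "FSE", "alpha", "D2",
                "lambda_max"]
        a = pd.DataFrame(rng.normal(size=(6, 8)) + 10, columns=cols)
        b = pd.DataFrame(rng.normal(size=(6, 8)) + 10, columns=cols)
        out = compare_measures(a, b)
        assert list(out.index) == cols
        assert {"true_mean", "true_sd", "inferred_mean", "inferred_sd",
                "p_value", "significant"} <= set(out.columns)

    def test_mismatched_tables_rejected(self, rng):
        a, b = self._table(rng)
        with pytest.raises(ValueError):
            compare_measures(a, b.iloc[:5])
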