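"""Linear and nonlinear posturographic sway measures.

Basic measures: mean distance MD, mean velocity MV, mean acceleration
MA and mean frequency MF = MV / (2 pi MD) of a zero-mean COM signal.

Nonlinear measures: fuzzy sample entropy (FSE, predictability),
detrended-fluctuation scaling exponent alpha (long-range
correlations), Grassberger-Procaccia correlation dimension D2
(active degrees of freedom) and the Rosenstein largest Lyapunov
exponent lambda_max (local divergence rate).  The latter two operate
on a delay embedding whose lag J is the first minimum of the mutual
information function, with a Theiler exclusion window of 2J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sp_stats


@dataclass(frozen=True)
class BasicMeasures:
    MD: float  # mean distance (mm)
    MV: float  # mean velocity (mm/s)
    MA: float  # mean acceleration (mm/s^2)
    MF: float  # mean frequency (Hz)


@dataclass(frozen=True)
class FseParams:
    """Fuzzy sample entropy parameters: template length L, tolerance
    r_tol and membership shape factor c_shape (on the SD-normalized
    signal)."""

    L: int = 6
    r_tol: float = 0.03
    c_shape: float = 0.01

    def __post_init__(self):
        if self.L < 1 or self.r_tol <= 0 or self.c_shape <= 0:
            raise ValueError("invalid fuzzy-entropy parameters")


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay embedding: lag J (samples), dimension M, Theiler window."""

    J: int
    M: int

    def __post_init__(self):
        if self.J < 1 or self.M < 1:
            raise ValueError("lag and dimension must be at least 1")

    @property
    def theiler(self) -> int:
        return 2 * self.J


@dataclass(frozen=True)
class NonlinearMeasures:
    FSE: float
    alpha: float
    D2: float
    lambda_max: float


def basic_measures(x, fs: float) -> BasicMeasures:
    """MD, MV, MA and MF of a (zero-mean, mm-scaled) sway signal.

    MD = mean |x|; MV = fs * mean |first difference|;
    MA = fs^2 * mean |second difference|; MF = MV / (2 pi MD).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    md = float(np.mean(np.abs(x)))
    mv = float(fs * np.mean(np.abs(np.diff(x))))
    ma = float(fs ** 2 * np.mean(np.abs(np.diff(x, n=2))))
    mf = mv / (2.0 * math.pi * md) if md > 0 else 0.0
    return BasicMeasures(MD=md, MV=mv, MA=ma, MF=mf)


@njit(cache=True)
def _fuzzy_counts(x, L, expo, c):
    # sums of fuzzy memberships over all i<j template pairs, for
    # template lengths L (B) and L+1 (A); both use n-L start points
    n = len(x)
    n_templates = n - L
    B = 0.0
    A = 0.0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            dL = 0.0
            for m in range(L):
                dif = abs(x[j + m] - x[i + m])
                if dif > dL:
                    dL = dif
            d1 = dL
            dif = abs(x[j + L] - x[i + L])
            if dif > d1:
                d1 = dif
            if dL > 0.0:
                B += math.exp(-(dL ** expo) / c)
            else:
                B += 1.0
            if d1 > 0.0:
                A += math.exp(-(d1 ** expo) / c)
            else:
                A += 1.0
    return A, B


def fuzzy_sample_entropy(x, p: FseParams = FseParams()) -> float:
    """Fuzzy sample entropy -ln(A_L / B_L) of a signal.

    Chebyshev distances between all pairs of templates of length L
    (count B) and L+1 (count A) enter a fuzzy membership
    mu(d) = exp(-d^q / c) with exponent q = ln(c ln 2)/ln(r), so the
    tolerance r is the distance at which mu = 1/2.  The signal is
    divided by its SD first, so r acts on normalized amplitude.
    Low FSE means predictable, repetitive sway.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= 2 * (p.L + 1):
        raise ValueError("signal too short for the requested template length")
    sd = x.std()
    if sd > 0:
        x = x / sd
    expo = math.log(p.c_shape * math.log(2.0)) / math.log(p.r_tol)
    A, B = _fuzzy_counts(np.ascontiguousarray(x), p.L, expo, p.c_shape)
    if A <= 0 or B <= 0:
        raise ValueError("undefined entropy: no template matches")
    return float(-math.log(A / B))


def dfa_alpha(x, s_min: int = 5, s_max: int = 750, n_scales: int = 20) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The signal is integrated (cumulative sum of deviations), split
    into non-overlapping windows of each scale s, linearly detrended
    per window, and the RMS residual F(s) computed; alpha is the
    least-squares slope of log F against log s.  White noise gives
    alpha ~ 0.5, Brownian motion ~ 1.5.
    """
    x = np.asarray(x, dtype=float)
    scales = np.unique(np.round(np.logspace(
        math.log10(s_min), math.log10(s_max), n_scales)).astype(int))
    scales = scales[(scales >= 4) & (scales <= len(x) // 2)]
    if len(scales) < 2:
        raise ValueError("too few usable scales for the signal length")
    y = np.cumsum(x - x.mean())
    logF = np.empty(len(scales), dtype=float)
    for si, s in enumerate(scales):
        n_win = len(y) // s
        seg = y[:n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        # per-window linear detrend via least squares on a common design
        A = np.column_stack([t, np.ones(s)])
        coef, *_ = np.linalg.lstsq(A, seg.T, rcond=None)
        resid = seg.T - A @ coef
        logF[si] = 0.5 * math.log10(float(np.mean(resid ** 2)))
    slope, _ = np.polyfit(np.log10(scales), logF, 1)
    return float(slope)


def mutual_information_lag(x, max_lag: int = 100, n_bins: int = 16) -> int:
    """Embedding lag J: first minimum of the mutual information.

    MI between x(t) and x(t+lag) is estimated on an n_bins x n_bins
    histogram for lags 1..max_lag; the curve is lightly smoothed
    (3-point moving average) to suppress binning jitter and J is its
    first local minimum (global minimum if none exists).
    """
    x = np.asarray(x, dtype=float)
    max_lag = min(max_lag, len(x) - 2)
    edges = np.histogram_bin_edges(x, bins=n_bins)
    mi = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        a, b = x[:-lag], x[lag:]
        h, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        p = h / h.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        mi[lag - 1] = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    smooth = np.convolve(mi, np.ones(3) / 3.0, mode="same")
    smooth[0], smooth[-1] = mi[0], mi[-1]
    for i in range(len(smooth)):
        left_ok = i == 0 or smooth[i] < smooth[i - 1]
        right_ok = i + 1 < len(smooth) and smooth[i] < smooth[i + 1]
        if left_ok and right_ok:
            return i + 1
    return int(np.argmin(smooth)) + 1


def _embed(x, J: int, M: int) -> np.ndarray:
    n = len(x) - (M - 1) * J
    if n < 2:
        raise ValueError("signal too short for the requested embedding")
    return np.column_stack([x[i * J:i * J + n] for i in range(M)])


@njit(cache=True)
def _correlation_sum(X, theiler, r_grid):
    n = X.shape[0]
    counts = np.zeros(len(r_grid))
    n_pairs = 0
    for i in range(n):
        for j in range(i + theiler + 1, n):
            d2 = 0.0
            for m in range(X.shape[1]):
                dif = X[i, m] - X[j, m]
                d2 += dif * dif
            d = math.sqrt(d2)
            n_pairs += 1
            for ri in range(len(r_grid)):
                if d < r_grid[ri]:
                    counts[ri] += 1.0
    return counts, n_pairs


def correlation_dimension(x, J: int | None = None, max_M: int = 12,
                          n_r: int = 75, n_decades: float = 5.0,
                          min_points: int = 5):
    """Grassberger-Procaccia correlation dimension with the
    embedding-saturation stopping rule.

    For increasing embedding dimension M the correlation sum C_M(r)
    (fraction of trajectory-point pairs closer than r, pairs within a
    Theiler window of 2J excluded) is fitted as a power law
    C_M ~ r^d_M over the small-r scaling region
    (C_M between 1e-3 and 1e-1 of its maximum, at least ``min_points``
    grid points).  The first M with M > 2 d_M + 1 stops the scan and
    d_M is reported as D2.

    Returns (D2, M_used, J_used).
    """
    x = np.asarray(x, dtype=float)
    if J is None:
        J = mutual_information_lag(x)
    theiler = 2 * J
    d_M = None
    for M in range(1, max_M + 1):
        X = np.ascontiguousarray(_embed(x, J, M))
        dmax = float(np.sqrt(M) * (x.max() - x.min()))
        r_grid = np.logspace(math.log10(dmax) - n_decades, math.log10(dmax), n_r)
        counts, n_pairs = _correlation_sum(X, theiler, r_grid)
        if n_pairs == 0:
            raise ValueError("no pairs outside the Theiler window")
        C = counts / n_pairs
        cmax = C.max()
        sel = (C >= 1e-3 * cmax) & (C <= 1e-1 * cmax) & (C > 0)
        if sel.sum() < min_points:
            raise ValueError(
                f"no scaling region at M={M}: only {int(sel.sum())} usable points")
        slope, _ = np.polyfit(np.log(r_grid[sel]), np.log(C[sel]), 1)
        d_M = float(slope)
        if M > 2.0 * d_M + 1.0:
            return d_M, M, J
    raise ValueError(f"correlation dimension did not saturate by M={max_M} "
                     f"(last d_M={d_M:.2f})")


@njit(cache=True)
def _divergence_curve(X, theiler, horizon):
    n = X.shape[0]
    sums = np.zeros(horizon)
    counts = np.zeros(horizon)
    for i in range(n):
        best = 1e300
        jbest = -1
        for j in range(n):
            if abs(i - j) <= theiler:
                continue
            d2 = 0.0
            for m in range(X.shape[1]):
                dif = X[i, m] - X[j, m]
                d2 += dif * dif
            if d2 < best and d2 > 0.0:
                best = d2
                jbest = j
        if jbest < 0:
            continue
        kmax = min(horizon, n - i, n - jbest)
        for s in range(kmax):
            d2 = 0.0
            for m in range(X.shape[1]):
                dif = X[i + s, m] - X[jbest + s, m]
                d2 += dif * dif
            if d2 > 0.0:
                sums[s] += 0.5 * math.log(d2)
                counts[s] += 1.0
    return sums, counts


def largest_lyapunov(x, spec: EmbeddingSpec, fs: float | None = None,
                     fit_range: tuple[int, int] | None = None) -> float:
    """Largest Lyapunov exponent by nearest-neighbor divergence.

    Each embedded point is paired with its nearest neighbor outside a
    Theiler window of 2J; the mean log distance between the paired
    trajectories is tracked forward and lambda_max is the least-squares
    slope of that curve over ``fit_range`` (default: the first J+1
    steps, the initial expansion region).  With ``fs`` given the slope
    is returned per second, otherwise per sample interval.
    """
    x = np.asarray(x, dtype=float)
    X = np.ascontiguousarray(_embed(x, spec.J, spec.M))
    if X.shape[0] < 100:
        raise ValueError("embedded trajectory too short (< 100 points)")
    if fit_range is None:
        fit_range = (0, spec.J)
    horizon = fit_range[1] + 1
    sums, counts = _divergence_curve(X, spec.theiler, horizon)
    ok = counts > 0
    if ok.sum() < 2:
        raise ValueError("no valid neighbor pairs for divergence tracking")
    steps = np.arange(horizon)[ok]
    curve = sums[ok] / counts[ok]
    in_fit = (steps >= fit_range[0]) & (steps <= fit_range[1])
    slope, _ = np.polyfit(steps[in_fit], curve[in_fit], 1)
    return float(slope * fs) if fs is not None else float(slope)


MEASURE_NAMES = ("MD_mm", "MV_mm_s", "MA_mm_s2", "MF_Hz",
                 "FSE", "alpha", "D2", "lambda_max")


def all_measures(trial, fse: FseParams = FseParams(),
                 lyap_per_second: bool = True) -> dict:
    """All eight sway measures of one (preprocessed) trial.

    The correlation-dimension scan can legitimately fail to saturate
    on noise-dominated signals (the slope keeps growing with the
    embedding dimension); D2 is then reported as NaN and the Lyapunov
    embedding falls back to dimension 6.
    """
    x = np.asarray(trial.samples, dtype=float)
    bm = basic_measures(x, trial.fs)
    J = mutual_information_lag(x)
    try:
        d2, M, J = correlation_dimension(x, J=J)
    except ValueError:
        d2, M = float("nan"), 6
    spec = EmbeddingSpec(J=J, M=M)
    lam = largest_lyapunov(x, spec, fs=trial.fs if lyap_per_second else None)
    return {
        "MD_mm": bm.MD, "MV_mm_s": bm.MV, "MA_mm_s2": bm.MA, "MF_Hz": bm.MF,
        "FSE": fuzzy_sample_entropy(x, fse),
        "alpha": dfa_alpha(x),
        "D2": d2,
        "lambda_max": lam,
    }


def compare_measures(true_values: pd.DataFrame, inferred_values: pd.DataFrame,
                     alpha_level: float = 0.05) -> pd.DataFrame:
    """Paired comparison of sway-measure tables from two sources.

    Both inputs are DataFrames with one row per subject and one column
    per measure (same columns, same subject order).  Returns one row
    per measure with mean +/- SD of both groups, the paired t-test
    p-value and a significance flag; identical groups yield an
    undefined (NaN) p-value, flagged not significant.
    """
    if list(true_values.columns) != list(inferred_values.columns):
        raise ValueError("measure tables must share the same columns")
    if len(true_values) != len(inferred_values):
        raise ValueError("measure tables must have equal length (paired design)")
    rows = []
    for col in true_values.columns:
        a = true_values[col].to_numpy(dtype=float)
        b = inferred_values[col].to_numpy(dtype=float)
        if np.allclose(a, b):
            p = float("nan")
        else:
            p = float(sp_stats.ttest_rel(a, b).pvalue)
        rows.append({
            "measure": col,
            "true_mean": a.mean(), "true_sd": a.std(ddof=1) if len(a) > 1 else 0.0,
            "inferred_mean": b.mean(),
            "inferred_sd": b.std(ddof=1) if len(b) > 1 else 0.0,
            "p_value": p,
            "significant": bool(p < alpha_level) if np.isfinite(p) else False,
        })
    return pd.DataFrame(rows).set_index("measure")
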