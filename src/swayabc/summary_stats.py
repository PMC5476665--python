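"""The 60-element sway summary vector and the ABC discrepancy.

A trial set is summarised by three 15-bin histograms (absolute COM
amplitude, velocity and acceleration, with per-subject bin edges from
0 to the observed maximum) plus the first 15 Welch power-spectral-
density points up to about 0.7 Hz, averaged over trials.  The PSD
block has the same length as each histogram so all four information
channels carry equal weight.  Two summary vectors are compared with
the bounded, scale-free discrepancy

    rho = (1/60) sum |phi_obs - phi_sim| / |phi_obs + phi_sim|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

BLOCKS = ("amp", "vel", "acc", "psd")
N_BINS = 15


def derivative_magnitudes(x, fs: float):
    """Absolute amplitude, velocity and acceleration series of a signal.

    Velocity is the scaled first difference fs*|x(i+1)-x(i)| and
    acceleration the scaled second difference fs^2*|x(i+2)-2x(i+1)+x(i)|
    (units mm, mm/s, mm/s^2 for x in mm).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    amp = np.abs(x)
    vel = fs * np.abs(np.diff(x))
    acc = fs ** 2 * np.abs(np.diff(x, n=2))
    return amp, vel, acc


@dataclass(frozen=True)
class BinEdges:
    """Per-subject histogram bin edges: 15 equal-width bins from zero
    to the maximum over the subject's measured trials, per quantity."""

    amp: np.ndarray
    vel: np.ndarray
    acc: np.ndarray

    def __post_init__(self):
        for name in ("amp", "vel", "acc"):
            e = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, e)
            if len(e) != N_BINS + 1 or np.any(np.diff(e) <= 0) or e[0] != 0:
                raise ValueError(f"{name} edges must be 16 strictly increasing values from 0")

    def matches(self, other: "BinEdges") -> bool:
        return all(np.allclose(getattr(self, n), getattr(other, n))
                   for n in ("amp", "vel", "acc"))


@dataclass
class SummaryVector:
    """A 60-element nonnegative summary of a trial set."""

    phi: np.ndarray
    edges: BinEdges
    freqs: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (4 * N_BINS,):
            raise ValueError("summary vector must have exactly 60 elements")
        if np.any(self.phi < 0):
            raise ValueError("summary elements must be non-negative")

    def block(self, name: str) -> np.ndarray:
        i = BLOCKS.index(name)
        return self.phi[i * N_BINS:(i + 1) * N_BINS]

    def to_record(self) -> dict:
        """Flat 60-column record keyed amp_01 ... psd_15."""
        out = {}
        for bi, name in enumerate(BLOCKS):
            for j in range(N_BINS):
                out[f"{name}_{j + 1:02d}"] = float(self.phi[bi * N_BINS + j])
        return out


def make_bin_edges(trials) -> BinEdges:
    """Bin edges from the maxima of a subject's (preprocessed) trials."""
    if not trials:
        raise ValueError("need at least one trial")
    maxima = np.zeros(3)
    for tr in trials:
        for q, series in enumerate(derivative_magnitudes(tr.samples, tr.fs)):
            maxima[q] = max(maxima[q], float(series.max()))
    if np.any(maxima <= 0):
        raise ValueError("degenerate (constant) signal: zero maximum, cannot form bins")
    lin = np.linspace(0.0, 1.0, N_BINS + 1)
    return BinEdges(amp=maxima[0] * lin, vel=maxima[1] * lin, acc=maxima[2] * lin)


def _welch_psd(x, fs: float, include_dc: bool = False):
    """First 15 Welch PSD points of a trial.

    Hamming window, 8 segments with 50% overlap, 1024-point FFT: at
    50 Hz the grid spacing is ~0.049 Hz, so points 1..15 (DC excluded)
    span ~0.049-0.73 Hz.
    """
    n = len(x)
    nperseg = max(16, int(n // 4.5))
    nfft = max(1024, nperseg)
    f, p = sp_signal.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                           noverlap=nperseg // 2, nfft=nfft)
    start = 0 if include_dc else 1
    return f[start:start + N_BINS], p[start:start + N_BINS]


def summarize(trials, edges: BinEdges, include_dc: bool = False) -> SummaryVector:
    """Summary vector of a trial set: histograms + PSD, trial-averaged.

    Values above the top bin edge are clipped into the last bin (so
    heavy-tailed candidate simulations are penalised, not ignored).
    Raises on fall-flagged trials; callers must screen those upstream.
    """
    if not trials:
        raise ValueError("need at least one trial")
    acc_phi = np.zeros(4 * N_BINS)
    freqs = None
    for tr in trials:
        if getattr(tr, "fell", False):
            raise ValueError("cannot summarize a fall-flagged trial")
        series = derivative_magnitudes(tr.samples, tr.fs)
        parts = []
        for q, name in enumerate(("amp", "vel", "acc")):
            e = getattr(edges, name)
            counts, _ = np.histogram(np.minimum(series[q], e[-1]), bins=e)
            parts.append(counts.astype(float))
        freqs, psd = _welch_psd(tr.samples, tr.fs, include_dc=include_dc)
        parts.append(psd)
        acc_phi += np.concatenate(parts)
    return SummaryVector(phi=acc_phi / len(trials), edges=edges, freqs=freqs)


def discrepancy(phi_obs: SummaryVector, phi_sim: SummaryVector,
                block: str | None = None) -> float:
    """Normalized relative error between two summary vectors.

    rho = (1/l) sum_i |a_i - b_i| / |a_i + b_i|, with 0/0 terms
    defined as 0.  Bounded in [0, 1], symmetric, and invariant to a
    common positive rescaling of both vectors.  ``block`` restricts
    the sum to one 15-element channel (l = 15).
    """
    if not phi_obs.edges.matches(phi_sim.edges):
        raise ValueError("summary vectors use different bin edges")
    if phi_obs.freqs is not None and phi_sim.freqs is not None \
            and not np.allclose(phi_obs.freqs, phi_sim.freqs):
        raise ValueError("summary vectors use different frequency grids")
    if block is None:
        a, b = phi_obs.phi, phi_sim.phi
    else:
        a, b = phi_obs.block(block), phi_sim.block(block)
    num = np.abs(a - b)
    den = np.abs(a + b)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(terms.mean())
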