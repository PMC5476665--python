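"""Trial file I/O, preprocessing and the COP-to-COM transform.

Posturographic trials are delimited text (CSV or TSV by extension)
with columns ``time_s`` and ``cop_ap_mm`` (or ``com_mm``); subject
metadata lives in a JSON sidecar with ``mass_kg`` and ``height_cm``.
Signals are millimeters at every file boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .model_core import G, SwayTrial


class TrialFormatError(ValueError):
    """Raised for malformed or inconsistent trial files."""


@dataclass
class CopTrial:
    """A measured center-of-pressure trial (anterior-posterior, mm)."""

    samples: np.ndarray
    fs: float
    subject_meta: dict | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase low-pass filter: windowed-sinc FIR run forward and
    backward (so the effective magnitude response is squared)."""

    cutoff: float = 10.0
    taps: int = 51

    def design(self, fs: float) -> np.ndarray:
        if self.cutoff >= fs / 2:
            raise ValueError("cutoff must lie below the Nyquist frequency")
        return sp_signal.firwin(self.taps, self.cutoff, fs=fs, window="hamming")


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_cop_trials(paths, fs: float = 50.0, expected_duration: float | None = 60.0,
                    duration_tol: float = 0.5,
                    value_column: str = "cop_ap_mm") -> list[CopTrial]:
    """Read a set of COP (or COM) trial files into CopTrial objects.

    Each file must contain columns ``time_s`` and ``value_column``
    (extra columns are ignored).  Sampling uniformity, finiteness and
    trial duration are validated; violations raise
    :class:`TrialFormatError` naming the file (and row, where
    applicable).
    """
    trials = []
    for p in map(Path, paths):
        try:
            df = pd.read_csv(p, sep=_delimiter(p))
        except pd.errors.EmptyDataError:
            raise TrialFormatError(f"{p}: empty file") from None
        for col in ("time_s", value_column):
            if col not in df.columns:
                raise TrialFormatError(f"{p}: missing required column '{col}'")
        if len(df) == 0:
            raise TrialFormatError(f"{p}: no data rows")
        bad = np.flatnonzero(~np.isfinite(df[value_column].to_numpy())
                             | ~np.isfinite(df["time_s"].to_numpy()))
        if bad.size:
            raise TrialFormatError(f"{p}: non-finite value at data row {bad[0] + 1}")
        t = df["time_s"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            if np.max(np.abs(dt - 1.0 / fs)) > 1e-6:
                raise TrialFormatError(f"{p}: non-uniform sampling (expected {1.0 / fs} s steps)")
        if expected_duration is not None:
            dur = len(t) / fs
            if abs(dur - expected_duration) > duration_tol:
                raise TrialFormatError(
                    f"{p}: trial duration {dur:.2f} s, expected {expected_duration} s")
        meta = None
        sidecar = p.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        trials.append(CopTrial(samples=df[value_column].to_numpy(), fs=fs,
                               subject_meta=meta))
    return trials


def write_trial(path, trial, column: str = "com_mm", meta: dict | None = None) -> None:
    """Write one trial as delimited text (plus optional JSON sidecar)."""
    path = Path(path)
    t = np.arange(len(trial.samples)) / trial.fs
    pd.DataFrame({"time_s": t, column: trial.samples}).to_csv(
        path, sep=_delimiter(path), index=False, float_format="%.6f")
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def preprocess(trial, spec: FilterSpec | None = None):
    """Zero-mean and zero-phase low-pass a trial.

    Returns a new object of the same type.  The mean is removed before
    and after filtering so the output is exactly zero-mean.
    """
    spec = spec or FilterSpec()
    x = np.asarray(trial.samples, dtype=float)
    if len(x) <= 3 * spec.taps:
        raise ValueError(f"signal length {len(x)} too short for a {spec.taps}-tap filter")
    taps = spec.design(trial.fs)
    y = sp_signal.filtfilt(taps, [1.0], x - x.mean())
    y = y - y.mean()
    if isinstance(trial, CopTrial):
        return CopTrial(samples=y, fs=trial.fs, subject_meta=trial.subject_meta)
    return SwayTrial(samples=y, fs=trial.fs, state=getattr(trial, "state", None))


def _exp_kernel(fs: float, h: float, rel_tol: float = 1e-8) -> np.ndarray:
    """Two-sided exponential COP->COM kernel, truncated and unit-sum.

    The analytic kernel (dt*sqrt(g/h)/2)*exp(-|t|*sqrt(g/h)) integrates
    to one; the discrete kernel is rescaled to unit sum so constant
    inputs pass through unchanged.
    """
    lam = math.sqrt(G / h)
    dt = 1.0 / fs
    half = int(math.ceil(-math.log(rel_tol) / (lam * dt)))
    n = np.arange(-half, half + 1)
    w = (dt * lam / 2.0) * np.exp(-np.abs(n) * dt * lam)
    return w / w.sum()


def cop_to_com(cop: CopTrial, h: float) -> SwayTrial:
    """Convert a measured COP trial to a COM trial.

    The COP is a second-order mechanical transform of the COM; the
    inverse mapping is a convolution with a symmetric two-sided
    exponential kernel of rate sqrt(g/h).  Edges are handled by
    reflective padding of one kernel half-width.
    """
    if h <= 0:
        raise ValueError("COM height must be positive")
    w = _exp_kernel(cop.fs, h)
    half = len(w) // 2
    x = np.asarray(cop.samples, dtype=float)
    pad = min(half, len(x) - 1)
    xp = np.pad(x, pad, mode="reflect")
    y = sp_signal.fftconvolve(xp, w, mode="same")[pad:pad + len(x)]
    return SwayTrial(samples=y, fs=cop.fs)
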