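"""Simulated test subjects for parameter-recovery studies.

Each subject is an anthropometric draw (mass, height) plus a true
control-parameter vector, with three simulated "measured" COM trials.
Anthropometrics come from normals around the cohort means
(66 +/- 17 kg, 169 +/- 12 cm) and are screened by the filters weight
40-110 kg, height 145-200 cm, BMI 15-35; control parameters come from
normals (P = 146 +/- 50 Nm/rad, D = 23 +/- 14 Nms/rad,
delta = 0.20 +/- 0.06 s, sigma = 0.21 +/- 0.10 Nm,
c_on = 0.65 +/- 0.05) truncated to the prior box so recovery is
always well-posed.  A draw is accepted only if its simulated sway
also passes the sway screens: maximum zero-mean amplitude 10-50 mm,
no fall, and a plausible mean sway frequency (0.02-1 Hz) standing in
for visual realism screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .model_core import ControlParams, PendulumPlant, SwayTrial, simulate_sway
from .signal_io import write_trial
from .smc_abc import PriorSpec
from .sway_measures import basic_measures


@dataclass(frozen=True)
class CohortSpec:
    """Cohort means and SDs (units: kg, cm, then the parameter units)."""

    mass: tuple = (66.0, 17.0)
    height_cm: tuple = (169.0, 12.0)
    P: tuple = (146.0, 50.0)
    D: tuple = (23.0, 14.0)
    delta: tuple = (0.20, 0.06)
    sigma: tuple = (0.21, 0.10)
    c_on: tuple = (0.65, 0.05)

    mass_bounds: tuple = (40.0, 110.0)
    height_bounds_cm: tuple = (145.0, 200.0)
    bmi_bounds: tuple = (15.0, 35.0)
    amplitude_bounds_mm: tuple = (10.0, 50.0)
    mf_bounds_hz: tuple = (0.02, 1.0)


@dataclass
class SyntheticSubject:
    subject_id: int
    plant: PendulumPlant
    true_params: ControlParams
    trials: list = field(repr=False, default_factory=list)
    seed: int = 0
    accepted: bool = True
    rejection_reason: str | None = None

    @property
    def mass_kg(self) -> float:
        return self.plant.m

    @property
    def height_cm(self) -> float:
        return self.plant.h_sub * 100.0


def _trunc_normal(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _screen(trials, spec: CohortSpec) -> str | None:
    if any(tr.fell for tr in trials):
        return "fell"
    max_amp = max(float(np.max(np.abs(tr.samples - tr.samples.mean())))
                  for tr in trials)
    if not spec.amplitude_bounds_mm[0] <= max_amp <= spec.amplitude_bounds_mm[1]:
        return "amplitude"
    for tr in trials:
        mf = basic_measures(tr.samples - tr.samples.mean(), tr.fs).MF
        if not spec.mf_bounds_hz[0] <= mf <= spec.mf_bounds_hz[1]:
            return "frequency"
    return None


def sample_subject(seed: int, cohort: CohortSpec = CohortSpec(),
                   prior: PriorSpec | None = None, duration: float = 60.0,
                   n_trials: int = 3, max_retries: int = 100,
                   subject_id: int = 0) -> SyntheticSubject:
    """Draw one accepted synthetic subject (resampling rejected draws).

    Anthropometrics and parameters come from independent truncated
    normals; truncation bounds are the screening limits intersected
    with the inference prior box.  Raises if ``max_retries`` draws all
    fail, reporting the dominant rejection reason.
    """
    prior = prior or PriorSpec()
    pb = prior.as_array()
    rng = np.random.default_rng(seed)
    reasons: dict[str, int] = {}
    for _ in range(max_retries):
        mass = float(rng.normal(*cohort.mass))
        height_cm = float(rng.normal(*cohort.height_cm))
        if not cohort.mass_bounds[0] <= mass <= cohort.mass_bounds[1]:
            reasons["weight"] = reasons.get("weight", 0) + 1
            continue
        if not cohort.height_bounds_cm[0] <= height_cm <= cohort.height_bounds_cm[1]:
            reasons["height"] = reasons.get("height", 0) + 1
            continue
        bmi = mass / (height_cm / 100.0) ** 2
        if not cohort.bmi_bounds[0] <= bmi <= cohort.bmi_bounds[1]:
            reasons["bmi"] = reasons.get("bmi", 0) + 1
            continue
        draws = [
            _trunc_normal(rng, *getattr(cohort, name), pb[i, 0], pb[i, 1])
            for i, name in enumerate(("P", "D", "delta", "sigma", "c_on"))
        ]
        params = ControlParams.from_array(draws)
        plant = PendulumPlant.from_anthropometrics(mass, height_cm / 100.0)
        trial_seed = int(rng.integers(0, 2 ** 31))
        trials = simulate_sway(plant, params, duration=duration,
                               seed=trial_seed, n_trials=n_trials)
        reason = _screen(trials, cohort)
        if reason is None:
            return SyntheticSubject(subject_id=subject_id, plant=plant,
                                    true_params=params, trials=trials,
                                    seed=trial_seed, accepted=True)
        reasons[reason] = reasons.get(reason, 0) + 1
    dominant = max(reasons, key=reasons.get) if reasons else "unknown"
    raise RuntimeError(
        f"no acceptable subject in {max_retries} draws "
        f"(dominant rejection reason: {dominant}, counts: {reasons})")


def generate_cohort(n: int = 10, seed: int = 0,
                    cohort: CohortSpec = CohortSpec(),
                    prior: PriorSpec | None = None, duration: float = 60.0,
                    n_trials: int = 3) -> list[SyntheticSubject]:
    """Generate n accepted subjects with distinct derived sub-seeds."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    root = np.random.SeedSequence(seed)
    subjects = []
    for i, child in enumerate(root.spawn(n)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        subjects.append(sample_subject(sub_seed, cohort=cohort, prior=prior,
                                       duration=duration, n_trials=n_trials,
                                       subject_id=i))
    return subjects


def cohort_manifest(subjects) -> pd.DataFrame:
    """True-parameter manifest, one row per subject."""
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id,
            "mass_kg": s.plant.m,
            "height_cm": (s.plant.h_sub or 0.0) * 100.0,
            "h_m": s.plant.h,
            "P": s.true_params.P, "D": s.true_params.D,
            "delta": s.true_params.delta, "sigma": s.true_params.sigma,
            "c_on": s.true_params.c_on,
            "seed": s.seed,
        })
    return pd.DataFrame(rows)


def write_cohort(subjects, out_dir) -> Path:
    """Write the manifest plus one trial file per signal."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(subjects)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    for s in subjects:
        for t, tr in enumerate(s.trials):
            write_trial(out_dir / f"subject{s.subject_id:02d}_trial{t + 1}.csv", tr,
                        meta={"mass_kg": s.plant.m,
                              "height_cm": (s.plant.h_sub or 0.0) * 100.0,
                              "seed": s.seed})
    return manifest_path
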