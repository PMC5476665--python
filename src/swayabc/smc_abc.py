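"""Likelihood-free inference of the control parameters by SMC-ABC.

The sway model's likelihood is intractable, but simulating it is
cheap, so inference proceeds by approximate Bayesian computation:
parameter draws are accepted when the discrepancy rho between the
observed and simulated summary vectors falls below a threshold
epsilon.  The sequential (population) Monte Carlo variant tightens
epsilon over iterations: each population is a weighted sample, new
candidates are drawn by perturbing resampled particles with an
adaptive Gaussian kernel, and importance weights correct for the
proposal.  The engine is generic over a loss function
``loss(theta, rng) -> rho`` so it can be validated on analytically
tractable toy problems; :func:`infer_params` wires it to the sway
simulator and summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model_core import ControlParams, PendulumPlant, simulate_sway
from .signal_io import FilterSpec, preprocess
from .summary_stats import SummaryVector, discrepancy, make_bin_edges, summarize

PARAM_NAMES = ("P", "D", "delta", "sigma", "c_on")


class AbcBudgetError(RuntimeError):
    """Simulation budget exhausted before enough acceptances."""


class AbcDegeneracyError(RuntimeError):
    """Particle population collapsed (effective sample size < 2)."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors on the five control parameters.

    Defaults: P in [50, 400] Nm/rad, D in [0.05, 50] Nms/rad,
    delta in [0.05, 0.5] s, sigma in [0.05, 0.6] Nm, and the level of
    control c_on in [0.50, 1.00] (a fraction).
    """

    bounds: tuple = (
        (50.0, 400.0),
        (0.05, 50.0),
        (0.05, 0.5),
        (0.05, 0.6),
        (0.50, 1.00),
    )
    names: tuple = PARAM_NAMES

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError("every prior lower bound must lie below its upper bound")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)

    def contains(self, theta) -> np.ndarray:
        b = self.as_array()
        theta = np.atleast_2d(theta)
        return np.all((theta >= b[:, 0]) & (theta <= b[:, 1]), axis=1)


@dataclass
class ParticlePopulation:
    """One weighted SMC-ABC population."""

    params: np.ndarray  # (N, k)
    weights: np.ndarray  # (N,), normalized
    rhos: np.ndarray  # (N,)
    epsilon: float
    n_sims: int
    iteration: int = 0

    @property
    def ess(self) -> float:
        """Effective sample size 1 / sum(w^2)."""
        return float(1.0 / np.sum(self.weights ** 2))


@dataclass
class PosteriorSummary:
    """Weighted marginal summaries of a particle population."""

    names: Sequence[str]
    mean: np.ndarray
    sd: np.ndarray
    ci50: np.ndarray  # (k, 2) central 50% interval
    ci95: np.ndarray  # (k, 2) central 95% interval
    density_grid: np.ndarray  # (k, m)
    density: np.ndarray  # (k, m)

    def to_dict(self) -> dict:
        return {
            name: {
                "mean": float(self.mean[i]),
                "sd": float(self.sd[i]),
                "ci50": [float(v) for v in self.ci50[i]],
                "ci95": [float(v) for v in self.ci95[i]],
            }
            for i, name in enumerate(self.names)
        }


def sample_prior(n: int, prior: PriorSpec, seed=None) -> np.ndarray:
    """Draw n i.i.d. parameter vectors from the uniform prior box."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = prior.as_array()
    return rng.uniform(b[:, 0], b[:, 1], size=(n, len(b)))


def _candidate_rng(seed: int, iteration: int, index: int) -> np.random.Generator:
    # per-candidate stream: reproducible and independent of evaluation order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(iteration, index)))


def rejection_abc(
    loss: Callable[[np.ndarray, np.random.Generator], float],
    prior: PriorSpec,
    n_accept: int,
    epsilon: float,
    seed: int = 0,
    max_sims: int | None = None,
) -> ParticlePopulation:
    """Plain rejection ABC: accept prior draws with loss <= epsilon.

    Serves as the transparent reference implementation the sequential
    sampler is checked against.  Candidates whose loss is non-finite
    (e.g. fall-flagged simulations) are never accepted.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if max_sims is None:
        max_sims = 200 * n_accept
    rng = np.random.default_rng(seed)
    accepted, rhos = [], []
    n_sims = 0
    while len(accepted) < n_accept:
        if n_sims >= max_sims:
            raise AbcBudgetError(
                f"{len(accepted)}/{n_accept} acceptances after {n_sims} simulations "
                f"(acceptance rate {len(accepted) / n_sims:.2e}) at epsilon={epsilon}")
        theta = sample_prior(1, prior, rng)[0]
        rho = loss(theta, _candidate_rng(seed, 0, n_sims))
        n_sims += 1
        if np.isfinite(rho) and rho <= epsilon:
            accepted.append(theta)
            rhos.append(rho)
    n = len(accepted)
    return ParticlePopulation(
        params=np.array(accepted), weights=np.full(n, 1.0 / n),
        rhos=np.array(rhos), epsilon=float(epsilon), n_sims=n_sims)


def smc_abc(
    loss: Callable[[np.ndarray, np.random.Generator], float],
    prior: PriorSpec,
    n_particles: int = 5000,
    n_iterations: int = 7,
    seed: int = 0,
    quantile: float = 0.25,
    max_sims_per_iteration: int | None = None,
) -> list[ParticlePopulation]:
    """Sequential Monte Carlo ABC with an adaptive threshold schedule.

    Iteration 1 draws a pilot sample from the prior and keeps the
    fraction ``quantile`` with the smallest losses (equivalently,
    rejection at the pilot q-quantile threshold).  Each later
    iteration sets epsilon to the weighted q-quantile of the previous
    population's losses (an aggressive quantile tightens epsilon
    toward the stochastic discrepancy floor in few iterations, at the
    price of a lower acceptance rate), resamples particles by weight,
    perturbs them with a multivariate Gaussian kernel whose
    covariance is twice the weighted covariance of the previous
    population, rejects proposals outside the prior box, and
    importance-weights acceptances with the standard SMC-ABC formula
    for uniform priors.

    Returns the populations of all iterations; epsilons decrease
    strictly.  Defaults (5000 particles, 7 iterations) match the
    protocol the package's study design targets; scale them down for
    quick runs.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    if n_particles < 2:
        raise ValueError("need at least two particles")
    if max_sims_per_iteration is None:
        max_sims_per_iteration = 200 * n_particles

    b = prior.as_array()
    k = len(b)
    populations: list[ParticlePopulation] = []

    # --- iteration 1: pilot prior sample, keep the best quantile ---
    # candidates with non-finite loss (e.g. fall-flagged simulations)
    # consume budget but can never be kept, so sample until enough
    # usable pilots exist
    n_finite_needed = int(np.ceil(n_particles / quantile))
    rng = np.random.default_rng(seed)
    pilot_thetas, pilot_rhos = [], []
    n_finite = 0
    n_sims = 0
    while n_finite < n_finite_needed:
        if n_sims >= max_sims_per_iteration:
            raise AbcBudgetError(
                f"iteration 1: only {n_finite}/{n_finite_needed} usable pilot "
                f"simulations after {n_sims} draws; prior may be incompatible "
                "with the data")
        theta = sample_prior(1, prior, rng)[0]
        rho = loss(theta, _candidate_rng(seed, 1, n_sims))
        n_sims += 1
        if np.isfinite(rho):
            pilot_thetas.append(theta)
            pilot_rhos.append(rho)
            n_finite += 1
    pilot_thetas = np.array(pilot_thetas)
    pilot_rhos = np.array(pilot_rhos)
    order = np.argsort(pilot_rhos)[:n_particles]
    eps = float(pilot_rhos[order].max())
    populations.append(ParticlePopulation(
        params=pilot_thetas[order], weights=np.full(n_particles, 1.0 / n_particles),
        rhos=pilot_rhos[order], epsilon=eps, n_sims=n_sims, iteration=1))

    # --- iterations 2..T: resample, perturb, tighten ---
    for t in range(2, n_iterations + 1):
        prev = populations[-1]
        eps_t = _weighted_quantile(prev.rhos, prev.weights, quantile)
        if not eps_t < prev.epsilon:
            eps_t = np.nextafter(prev.epsilon, 0.0)
        # multivariate Gaussian kernel, covariance = 2x the weighted
        # empirical covariance of the previous population (proposals
        # then respect posterior correlations between parameters)
        mu = np.average(prev.params, axis=0, weights=prev.weights)
        dev = prev.params - mu
        cov = 2.0 * (dev.T * prev.weights) @ dev
        cov += np.eye(k) * (1e-12 * np.trace(cov) / k + 1e-300)
        L = np.linalg.cholesky(cov)
        Linv = np.linalg.inv(L)

        new_params = np.empty((n_particles, k))
        new_rhos = np.empty(n_particles)
        n_acc = 0
        n_sims = 0
        while n_acc < n_particles:
            if n_sims >= max_sims_per_iteration:
                raise AbcBudgetError(
                    f"iteration {t}: {n_acc}/{n_particles} acceptances after "
                    f"{n_sims} simulations at epsilon={eps_t:.4g}")
            # resample + perturb until the proposal lands in the prior box
            while True:
                j = rng.choice(n_particles, p=prev.weights)
                theta = prev.params[j] + L @ rng.standard_normal(k)
                if prior.contains(theta)[0]:
                    break
            rho = loss(theta, _candidate_rng(seed, t, n_sims))
            n_sims += 1
            if np.isfinite(rho) and rho <= eps_t:
                new_params[n_acc] = theta
                new_rhos[n_acc] = rho
                n_acc += 1
        # importance weights: uniform prior / Gaussian mixture proposal
        logw = np.empty(n_particles)
        for i in range(n_particles):
            z = (new_params[i] - prev.params) @ Linv.T
            logk = -0.5 * np.sum(z * z, axis=1)
            m = logk.max()
            logw[i] = -(m + np.log(np.sum(prev.weights * np.exp(logk - m))))
        w = np.exp(logw - logw.max())
        w /= w.sum()
        pop = ParticlePopulation(params=new_params, weights=w, rhos=new_rhos,
                                 epsilon=float(eps_t), n_sims=n_sims, iteration=t)
        if pop.ess < 2.0:
            raise AbcDegeneracyError(
                f"iteration {t}: effective sample size {pop.ess:.2f} < 2 "
                f"(epsilon={eps_t:.4g}, n_sims={n_sims})")
        populations.append(pop)
    return populations


def _weighted_var(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    mu = np.average(x, axis=0, weights=w)
    return np.average((x - mu) ** 2, axis=0, weights=w)


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(np.asarray(w)[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, np.asarray(x)[order]))


def posterior_summary(pop: ParticlePopulation, prior: PriorSpec | None = None,
                      names: Sequence[str] = PARAM_NAMES,
                      n_grid: int = 200) -> PosteriorSummary:
    """Weighted marginal summaries (mean, SD, central CIs, KDE).

    Densities use a Gaussian kernel with Silverman's bandwidth on the
    weighted SD, evaluated on (and renormalised over) the prior range
    when a prior is given, else over the sample range.
    """
    if len(pop.params) == 0:
        raise ValueError("empty population")
    x, w = pop.params, pop.weights
    k = x.shape[1]
    names = tuple(names)[:k]
    mean = np.average(x, axis=0, weights=w)
    sd = np.sqrt(_weighted_var(x, w))
    ci50 = np.array([[_weighted_quantile(x[:, d], w, q) for q in (0.25, 0.75)]
                     for d in range(k)])
    ci95 = np.array([[_weighted_quantile(x[:, d], w, q) for q in (0.025, 0.975)]
                     for d in range(k)])
    bounds = prior.as_array() if prior is not None else np.column_stack(
        [x.min(axis=0), x.max(axis=0)])
    grid = np.linspace(bounds[:, 0], bounds[:, 1], n_grid).T
    dens = np.zeros_like(grid)
    neff = pop.ess
    for d in range(k):
        bw = 1.06 * max(sd[d], 1e-12) * neff ** (-1 / 5)
        z = (grid[d][:, None] - x[None, :, d]) / bw
        dens[d] = (w[None, :] * np.exp(-0.5 * z * z)).sum(axis=1) / (
            bw * np.sqrt(2 * np.pi))
        area = np.trapezoid(dens[d], grid[d])
        if area > 0:
            dens[d] /= area
    return PosteriorSummary(names=names, mean=mean, sd=sd, ci50=ci50, ci95=ci95,
                            density_grid=grid, density=dens)


# ---------------------------------------------------------------------------
# Sway-model front end
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol for candidate evaluations: by default three
    60-s trials at 50 Hz, mirroring the measurement protocol."""

    n_trials: int = 3
    duration: float = 60.0
    fs: float = 50.0
    dt: float | None = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    include_dc: bool = False


def make_sway_loss(observed: SummaryVector, plant: PendulumPlant,
                   sim: SimConfig = SimConfig()) -> Callable:
    """Loss function theta -> rho against an observed summary vector.

    Simulates the candidate's trials, preprocesses them with the same
    filter as the observations, summarises them with the *observed*
    subject's bin edges (required for comparability) and returns the
    discrepancy; fall-flagged candidates get rho = inf.
    """

    def loss(theta: np.ndarray, rng: np.random.Generator) -> float:
        params = ControlParams.from_array(theta)
        trials = simulate_sway(plant, params, duration=sim.duration, dt=sim.dt,
                               seed=rng, n_trials=sim.n_trials, fs=sim.fs)
        if any(tr.fell for tr in trials):
            return np.inf
        trials = [preprocess(tr, sim.filter_spec) for tr in trials]
        phi = summarize(trials, observed.edges, include_dc=sim.include_dc)
        return discrepancy(observed, phi)

    return loss


def observed_summary(trials, sim: SimConfig = SimConfig()) -> SummaryVector:
    """Preprocess measured/simulated trials and build their summary
    vector with bin edges derived from those same trials."""
    prepped = [preprocess(tr, sim.filter_spec) for tr in trials]
    edges = make_bin_edges(prepped)
    return summarize(prepped, edges, include_dc=sim.include_dc)


def infer_params(
    trials,
    plant: PendulumPlant,
    prior: PriorSpec | None = None,
    n_particles: int = 5000,
    n_iterations: int = 7,
    seed: int = 0,
    sim: SimConfig = SimConfig(),
    quantile: float = 0.25,
) -> tuple[list[ParticlePopulation], PosteriorSummary]:
    """Full inference pipeline for one subject.

    Summarises the subject's COM trials, runs SMC-ABC against the sway
    simulator, and returns all populations plus the final posterior
    summary (posterior means are the point estimates).
    """
    prior = prior or PriorSpec()
    obs = observed_summary(trials, sim)
    loss = make_sway_loss(obs, plant, sim)
    pops = smc_abc(loss, prior, n_particles=n_particles,
                   n_iterations=n_iterations, seed=seed, quantile=quantile)
    return pops, posterior_summary(pops[-1], prior)
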