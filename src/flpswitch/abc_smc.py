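"""Approximate Bayesian computation by sequential Monte Carlo.

Population 1 is drawn from the uniform [0,1]^p prior and filtered by the
first error threshold; each later population resamples the previous one by
its importance weights, perturbs with a component-wise kernel, rejects
proposals outside the prior box before simulating, and accepts particles
whose fitting distance (the same d used by the GA) falls below the current
epsilon.  Importance weights follow the standard SMC update: uniform prior
density over the kernel-weighted mixture of the previous population.

A run ends either after the full schedule or as soon as a population cannot
be filled within the draw budget; the last completed population is returned
with a termination report, mirroring inference runs that stall at a final
threshold chosen at a previously attained optimisation error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import TimeCourseDataset
from .ga import DEFAULT_DOSE_MAP, _check_datasets, error_distance, simulate_datasets
from .observables import DoseCondition, SimulationError, SolverConfig
from .reduced import FITTED_PARAMETER_NAMES, ReducedParameters

__all__ = ["ABCConfig", "ABCPopulation", "ABCResult", "abc_smc",
           "posterior_summary", "weighted_quantile"]

logger = logging.getLogger(__name__)

#: schedule used to vet a previously attained optimisation error of 28.15
REFERENCE_EPSILON_SCHEDULE = (500.0, 250.0, 100.0, 50.0, 45.0, 40.0, 35.0,
                              30.0, 29.0, 28.15)


@dataclass(frozen=True)
class ABCConfig:
    n_particles: int = 100
    epsilon_schedule: tuple[float, ...] = REFERENCE_EPSILON_SCHEDULE
    seed: int = 0
    #: Gaussian kernel scale = kernel_scale_factor * weighted std of the
    #: previous population, per parameter (floored to avoid degeneracy);
    #: sqrt(2) gives the classic "twice the empirical variance" proposal
    kernel: str = "gaussian"  # "gaussian" | "uniform"
    kernel_scale_factor: float = 1.4142135623730951
    kernel_scale_floor: float = 1e-3
    max_draws: int = 200_000
    prior_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        eps = self.epsilon_schedule
        if len(eps) == 0 or any(b >= a for a, b in zip(eps, eps[1:])):
            raise ValueError("epsilon schedule must be non-empty and strictly decreasing")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.kernel not in ("gaussian", "uniform"):
            raise ValueError("kernel must be 'gaussian' or 'uniform'")


@dataclass(frozen=True)
class ABCPopulation:
    """Accepted particles at one threshold, with importance weights."""

    epsilon: float
    particles: np.ndarray        # (n, p)
    weights: np.ndarray          # (n,), sums to 1
    errors: np.ndarray           # (n,), all < epsilon
    particles_assessed: int

    @property
    def acceptance_percent(self) -> float:
        return 100.0 * len(self.particles) / self.particles_assessed

    def parameter_names(self) -> tuple[str, ...]:
        return FITTED_PARAMETER_NAMES


@dataclass(frozen=True)
class ABCResult:
    populations: tuple[ABCPopulation, ...]
    converged: bool
    #: epsilon at which the run stalled (None if the schedule completed)
    stalled_epsilon: float | None

    def log_table(self) -> list[dict]:
        """Acceptance log shaped as (epsilon, particles assessed, accepted %)."""
        return [{"epsilon": p.epsilon,
                 "particles_assessed": p.particles_assessed,
                 "acceptance_percent": p.acceptance_percent}
                for p in self.populations]


def abc_smc(datasets: Sequence[TimeCourseDataset],
            config: ABCConfig | None = None,
            dose_map: DoseCondition = DEFAULT_DOSE_MAP,
            solver: SolverConfig | None = None) -> ABCResult:
    config = config or ABCConfig()
    solver = solver or SolverConfig(rtol=1e-7, atol=1e-9)
    datasets = _check_datasets(datasets)
    observed = [d.percent_car for d in datasets]
    rng = np.random.default_rng(config.seed)
    lo, hi = config.prior_bounds
    n_par = len(FITTED_PARAMETER_NAMES)

    def distance(theta: np.ndarray) -> float:
        try:
            params = ReducedParameters.from_fitted_vector(theta)
            preds = simulate_datasets(params, datasets, dose_map, solver)
        except (SimulationError, ValueError):
            return np.inf
        return error_distance(preds, observed)

    populations: list[ABCPopulation] = []
    prev: ABCPopulation | None = None
    for epsilon in config.epsilon_schedule:
        accepted, errors = [], []
        assessed = 0
        if prev is not None:
            scales = _kernel_scales(prev, config)
        while len(accepted) < config.n_particles and assessed < config.max_draws:
            if prev is None:
                theta = rng.uniform(lo, hi, size=n_par)
            else:
                theta = _propose(rng, prev, scales, config)
            assessed += 1
            err = distance(theta)
            if err < epsilon:
                accepted.append(theta)
                errors.append(err)
        if len(accepted) < config.n_particles:
            logger.info("threshold %.4g not filled within %d draws; stopping",
                        epsilon, config.max_draws)
            return ABCResult(tuple(populations), False, epsilon)
        particles = np.array(accepted)
        if prev is None:
            weights = np.full(len(particles), 1.0 / len(particles))
        else:
            weights = _smc_weights(particles, prev, scales, config)
        pop = ABCPopulation(epsilon, particles, weights, np.array(errors), assessed)
        populations.append(pop)
        logger.info("epsilon %.4g: %d assessed, acceptance %.2f%%",
                    epsilon, assessed, pop.acceptance_percent)
        prev = pop
    return ABCResult(tuple(populations), True, None)


def _kernel_scales(prev: ABCPopulation, config: ABCConfig) -> np.ndarray:
    mean = np.average(prev.particles, axis=0, weights=prev.weights)
    var = np.average((prev.particles - mean) ** 2, axis=0, weights=prev.weights)
    return np.maximum(config.kernel_scale_factor * np.sqrt(var),
                      config.kernel_scale_floor)


def _propose(rng, prev: ABCPopulation, scales, config: ABCConfig) -> np.ndarray:
    """Weighted resample + perturb, re-proposing until inside the prior box."""
    lo, hi = config.prior_bounds
    while True:
        j = rng.choice(len(prev.particles), p=prev.weights)
        if config.kernel == "gaussian":
            theta = prev.particles[j] + rng.normal(0.0, scales)
        else:
            theta = prev.particles[j] + rng.uniform(-scales, scales)
        if np.all(theta >= lo) and np.all(theta <= hi):
            return theta


def _smc_weights(particles, prev: ABCPopulation, scales,
                 config: ABCConfig) -> np.ndarray:
    """w_i proportional to prior(theta_i) / sum_j w_j K(theta_i | theta_j)."""
    diff = particles[:, None, :] - prev.particles[None, :, :]  # (n, m, p)
    if config.kernel == "gaussian":
        z = diff / scales
        log_k = -0.5 * np.sum(z ** 2, axis=2) - np.sum(np.log(scales))
        dens = np.exp(log_k)
    else:
        inside = np.all(np.abs(diff) <= scales, axis=2)
        dens = inside / np.prod(2.0 * scales)
    mixture = dens @ prev.weights
    w = 1.0 / np.maximum(mixture, 1e-300)  # uniform prior: constant numerator
    return w / w.sum()


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Weighted quantile with linear interpolation at midpoint positions.

    Two equally weighted particles at 0 and 1 give a median of 0.5.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    pos = (cum - 0.5 * w) / cum[-1]
    return np.interp(np.asarray(q, dtype=float), pos, v)


def posterior_summary(population: ABCPopulation,
                      quantiles=(0.05, 0.25, 0.5, 0.75, 0.95),
                      n_bins: int = 20) -> dict:
    """Weighted marginal quantiles and histogram data per parameter."""
    if len(population.particles) == 0:
        raise ValueError("empty population")
    out = {}
    for j, name in enumerate(FITTED_PARAMETER_NAMES):
        vals = population.particles[:, j]
        qs = weighted_quantile(vals, population.weights, quantiles)
        hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0),
                                   weights=population.weights)
        out[name] = {
            "quantiles": dict(zip((f"q{int(100 * q):02d}" for q in quantiles),
                                  np.atleast_1d(qs).tolist())),
            "histogram": hist.tolist(),
            "bin_edges": edges.tolist(),
        }
    return out
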