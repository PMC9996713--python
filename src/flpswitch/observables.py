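"""Time integration and the switch observables.

Two observables drive every analysis:

* **percent CAR expression** — the fraction of chromosomal DNA in
  CAR-expressing genetic states, scaled to [0, 100].  The ON construct
  expresses from the transient inversion states and State 2; the mirrored
  OFF construct expresses only from State 1.  Both constructs share one
  dynamical system; only the readout differs.
* **response time** — time for the ON switch to reach 90% of its maximum
  percent CAR over the horizon, and for the OFF switch to achieve 90% of its
  total decrease.  Series that never move (e.g. uninduced, leak-free runs)
  are reported as censored at the horizon rather than clipped silently.

Dosing: the 4-OHT concentration enters the model as a source rate alpha_d
(media containing inducer are continuously replenished) and optionally as an
initial inducer amount; both channels scale linearly with the micromolar dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

from .datasets import TimeCourseDataset
from .mechanistic import (ReactionNetwork, build_mechanistic_network,
                          mechanistic_initial_state, state_totals)
from .reduced import (STATE_NAMES, ReducedParameters, reduced_initial_state,
                      reduced_rhs_vector)

__all__ = [
    "DoseCondition",
    "SolverConfig",
    "Trajectory",
    "SimulationError",
    "simulate",
    "percent_car",
    "response_time",
    "ResponseTimeResult",
    "normalize_to_global_max",
    "DEFAULT_HORIZON_DAYS",
]

DEFAULT_HORIZON_DAYS = 10.0


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the solver diagnostics."""


@dataclass(frozen=True)
class DoseCondition:
    """Linear map from a micromolar 4-OHT dose to the model input channels.

    ``alpha_d = alpha_d_at_1uM * dose_uM`` (a.u./day) and
    ``OHT(0) = oht0_at_1uM * dose_uM`` (a.u.).  The default drives the system
    through the source rate only, matching continuous media replenishment.
    """

    dose_uM: float
    alpha_d_at_1uM: float = 1.0
    oht0_at_1uM: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_uM < 0:
            raise ValueError("dose_uM must be >= 0")

    @property
    def alpha_d(self) -> float:
        return self.alpha_d_at_1uM * self.dose_uM

    @property
    def oht0(self) -> float:
        return self.oht0_at_1uM * self.dose_uM

    def at_dose(self, dose_uM: float) -> "DoseCondition":
        return replace(self, dose_uM=dose_uM)


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    mxstep: int = 100_000

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course: ``y[i, j]`` is species ``columns[j]`` at ``t[i]``."""

    t: np.ndarray
    y: np.ndarray
    model: str  # "reduced" | "mechanistic"
    columns: tuple[str, ...]
    network: ReactionNetwork | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("trajectory states must be finite")

    def series(self, name: str) -> np.ndarray:
        return self.y[:, self.columns.index(name)]


@dataclass(frozen=True)
class ResponseTimeResult:
    """90%-of-change response time in days; censored if never attained."""

    value: float
    censored: bool
    horizon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= self.horizon:
            raise ValueError("response time must lie in [0, horizon]")


def _default_grid(horizon: float = DEFAULT_HORIZON_DAYS) -> np.ndarray:
    return np.linspace(0.0, horizon, 501)


def simulate(model: str, params, dose: DoseCondition | None = None,
             t_grid=None, solver: SolverConfig | None = None,
             total_dna: float = 1.0) -> Trajectory:
    """Integrate the reduced or mechanistic model from the standard start state.

    The start state holds all DNA in free State 1 with no FlpO; ``dose``
    supplies the inducer source rate and initial amount (overriding any
    ``alpha_d`` already in ``params``).
    """
    if t_grid is None:
        t_grid = _default_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    solver = solver or SolverConfig()
    if model == "reduced":
        return _simulate_reduced(params, dose, t_grid, solver, total_dna)
    if model == "mechanistic":
        return _simulate_mechanistic(params, dose, t_grid, solver, total_dna)
    raise ValueError(f"unknown model {model!r}")


def _simulate_reduced(params: ReducedParameters, dose, t_grid, solver,
                      total_dna) -> Trajectory:
    if dose is not None:
        params = params.with_dose_rate(dose.alpha_d)
        oht0 = dose.oht0
    else:
        oht0 = 0.0
    y0 = reduced_initial_state(oht0, total_dna).to_vector()
    t, prepend = (t_grid, False)
    if t[0] != 0.0:
        t, prepend = (np.concatenate([[0.0], t]), True)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            out, info = odeint(
                lambda y, _t: reduced_rhs_vector(y, params), y0, t,
                rtol=solver.rtol, atol=solver.atol, mxstep=solver.mxstep,
                full_output=True)
        except Warning as w:  # odeint signals trouble via ODEintWarning
            raise SimulationError(f"reduced-model integration failed: {w}") from w
    if info["message"] != "Integration successful." or not np.all(np.isfinite(out)):
        raise SimulationError(f"reduced-model integration failed: {info['message']}")
    if prepend:
        out = out[1:]
    return Trajectory(t_grid, out, "reduced", STATE_NAMES)


def _simulate_mechanistic(params, dose, t_grid, solver, total_dna) -> Trajectory:
    if isinstance(params, ReactionNetwork):
        network = params
        if dose is not None and dose.alpha_d != network.params.alpha_d:
            network = build_mechanistic_network(
                replace(network.params, alpha_d=dose.alpha_d))
    else:
        if dose is not None:
            params = replace(params, alpha_d=dose.alpha_d)
        network = build_mechanistic_network(params)
    y0 = mechanistic_initial_state(network, dose.oht0 if dose else 0.0, total_dna)
    rhs = _compiled_rhs(network)
    sol = solve_ivp(rhs, (min(0.0, t_grid[0]), t_grid[-1]), y0, method="LSODA",
                    t_eval=t_grid, rtol=solver.rtol, atol=solver.atol,
                    max_step=solver.max_step)
    if not sol.success:
        raise SimulationError(f"mechanistic integration failed: {sol.message}")
    return Trajectory(t_grid, sol.y.T, "mechanistic",
                      tuple(s.name for s in network.species), network)


def _compiled_rhs(network: ReactionNetwork):
    """Vectorised mass-action RHS (index-array form of the per-reaction flux)."""
    n = network.n_species
    rates = network.rate_vector
    i1 = np.full(len(network.reactions), n, dtype=int)  # n -> padded 1.0
    i2 = np.full(len(network.reactions), n, dtype=int)
    for j, rxn in enumerate(network.reactions):
        idx = []
        for s, order in rxn.reactants:
            idx.extend([network.index[s]] * order)
        if len(idx) > 2:
            raise ValueError("reactions must be at most bimolecular")
        if len(idx) >= 1:
            i1[j] = idx[0]
        if len(idx) == 2:
            i2[j] = idx[1]
    S = network.stoichiometry_matrix

    def rhs(_t, y):
        yp = np.concatenate([y, [1.0]])
        return S @ (rates * yp[i1] * yp[i2])

    return rhs


def percent_car(traj: Trajectory, orientation: str) -> np.ndarray:
    """Percent of chromosomal DNA in CAR-expressing states along a trajectory.

    Reduced model: ON = 100*(D_tS1+D_tS2+D_S2)/total, OFF = 100*D_S1/total.
    Mechanistic model: the groups are the weighted aggregates of
    :func:`flpswitch.mechanistic.state_totals`.
    """
    if orientation not in ("ON", "OFF"):
        raise ValueError("orientation must be 'ON' or 'OFF'")
    if traj.model == "reduced":
        s1 = traj.series("D_S1")
        expressing = (traj.series("D_tS1") + traj.series("D_tS2")
                      + traj.series("D_S2"))
    else:
        totals = np.array([state_totals(traj.network, row) for row in traj.y])
        s1, expressing = totals[:, 0], totals[:, 1]
    denom = s1 + expressing
    if np.any(denom <= 0):
        raise ValueError("zero genomic total: percent CAR is undefined")
    frac = expressing / denom if orientation == "ON" else s1 / denom
    return 100.0 * frac


def response_time(times, values, orientation: str,
                  horizon: float | None = None) -> ResponseTimeResult:
    """Earliest time at which 90% of the series' change is attained.

    ON: first t with value(t) >= 0.9 * max over the horizon. OFF: first t
    with value(0) - value(t) >= 0.9 * (value(0) - min over the horizon).
    Linear interpolation between samples. A series with no rise (ON) or no
    decrease (OFF) is censored at the horizon.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0 or values.size == 0:
        raise ValueError("empty series")
    if times.shape != values.shape:
        raise ValueError("times and values must have the same length")
    if orientation not in ("ON", "OFF"):
        raise ValueError("orientation must be 'ON' or 'OFF'")
    if horizon is None:
        horizon = float(times[-1])
    mask = times <= horizon
    t, v = times[mask], values[mask]
    if t.size == 0:
        raise ValueError("no samples within the horizon")
    if orientation == "ON":
        target = 0.9 * float(np.max(v))
        if np.max(v) <= 0.0:
            return ResponseTimeResult(horizon, True, horizon)
        reached = v >= target
    else:
        drop = float(v[0] - np.min(v))
        if drop <= 0.0:
            return ResponseTimeResult(horizon, True, horizon)
        target = v[0] - 0.9 * drop
        reached = v <= target
    if not reached.any():
        return ResponseTimeResult(horizon, True, horizon)
    k = int(np.argmax(reached))
    if k == 0:
        return ResponseTimeResult(float(t[0]), False, horizon)
    # linear interpolation on the crossing segment
    t0, t1 = t[k - 1], t[k]
    v0, v1 = v[k - 1], v[k]
    if v1 == v0:
        tc = t1
    else:
        tc = t0 + (target - v0) * (t1 - t0) / (v1 - v0)
    tc = float(np.clip(tc, t0, t1))
    return ResponseTimeResult(tc, False, horizon)


def normalize_to_global_max(
        datasets: Sequence[TimeCourseDataset]) -> list[TimeCourseDataset]:
    """Rescale all series jointly so the single largest value maps to 100.

    This is the normalization used to restrict attention to functionally
    viable (recombinase- and switch-positive) cells: the global maximum over
    all four series is taken as the fully-ON reference.
    """
    if not datasets:
        raise ValueError("no datasets given")
    gmax = max(float(np.max(d.percent_car)) for d in datasets)
    if gmax <= 0:
        raise ValueError("all values are zero; global-max normalization undefined")
    # divide before scaling so the maximum maps to exactly 100.0 and no value
    # overshoots the upper bound by rounding
    return [d.with_values(d.percent_car / gmax * 100.0) for d in datasets]
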