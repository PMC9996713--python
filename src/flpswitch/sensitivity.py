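"""Post-fit analyses: parameter sensitivity, dose-response, expression tuning.

All analyses are one-at-a-time, deterministic scans over the reduced model:

* :func:`sensitivity_scan` perturbs each fitted rate constant multiplicatively
  over up to two orders of magnitude either side of its value and records the
  90% response time of both switches at the induced dose; parameters are
  ranked by the largest absolute log-change they cause.
* :func:`dose_response` sweeps the 4-OHT dose (default 1e-1..1e1 uM) and
  records both response times, exposing the inverse dose/response-time
  relationship.
* :func:`fold_change_scan` scales FlpO expression (alpha_a and alpha_b
  jointly, as one promoter-strength knob) and returns full time courses at
  the induced and uninduced doses, showing both the faster response and the
  increased basal switching that stronger promoters buy.
* :func:`tradeoff_grid` crosses expression fold changes with dose, one
  response-time matrix per switch, censored cells held at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .observables import (DEFAULT_HORIZON_DAYS, DoseCondition, SolverConfig,
                          SimulationError, percent_car, response_time, simulate)
from .reduced import FITTED_PARAMETER_NAMES, ReducedParameters

__all__ = ["SensitivityTable", "DoseResponseCurve", "TradeoffGrid",
           "sensitivity_scan", "dose_response", "fold_change_scan",
           "tradeoff_grid", "default_factor_grid", "default_dose_grid"]


def default_factor_grid() -> np.ndarray:
    """Nine log-spaced factors per side across two decades, plus the identity."""
    return np.logspace(-2.0, 2.0, 19)


def default_dose_grid(n: int = 13) -> np.ndarray:
    return np.logspace(-1.0, 1.0, n)


def _response_times(params: ReducedParameters, dose: DoseCondition,
                    horizon: float, solver: SolverConfig | None,
                    n_grid: int = 501):
    """(ON, OFF) response-time results from one integration at ``dose``."""
    t_grid = np.linspace(0.0, horizon, n_grid)
    traj = simulate("reduced", params, dose, t_grid, solver)
    on = response_time(t_grid, percent_car(traj, "ON"), "ON", horizon)
    off = response_time(t_grid, percent_car(traj, "OFF"), "OFF", horizon)
    return on, off


@dataclass(frozen=True)
class SensitivityTable:
    """Long-format scan results plus the derived parameter ranking."""

    parameters: tuple[str, ...]
    factors: np.ndarray
    on_times: np.ndarray        # (n_params, n_factors)
    off_times: np.ndarray
    on_censored: np.ndarray
    off_censored: np.ndarray
    baseline_on: float
    baseline_off: float
    horizon: float

    def max_log_change(self) -> dict[str, float]:
        """Largest |log10 response-time fold change| per parameter."""
        out = {}
        for i, name in enumerate(self.parameters):
            with np.errstate(divide="ignore"):
                d_on = np.abs(np.log10(self.on_times[i] / self.baseline_on))
                d_off = np.abs(np.log10(self.off_times[i] / self.baseline_off))
            out[name] = float(np.max(np.concatenate([d_on, d_off])))
        return out

    def ranking(self) -> list[str]:
        """Parameters ordered from most to least influential on response time."""
        changes = self.max_log_change()
        return sorted(changes, key=lambda n: -changes[n])

    def to_records(self) -> list[dict]:
        rows = []
        for i, name in enumerate(self.parameters):
            for j, f in enumerate(self.factors):
                rows.append({
                    "parameter": name, "factor": float(f),
                    "on_response_time": float(self.on_times[i, j]),
                    "off_response_time": float(self.off_times[i, j]),
                    "on_censored": bool(self.on_censored[i, j]),
                    "off_censored": bool(self.off_censored[i, j]),
                })
        return rows


def sensitivity_scan(params: ReducedParameters,
                     factor_grid=None,
                     horizon: float = DEFAULT_HORIZON_DAYS,
                     dose: DoseCondition | None = None,
                     solver: SolverConfig | None = None) -> SensitivityTable:
    """One-at-a-time multiplicative perturbation of every fitted parameter.

    Censored scans (the switch never attains 90% of its change within the
    horizon) enter the table at the horizon value with their flag set; a
    solver failure at a grid point is likewise recorded as censored.
    """
    factors = np.asarray(default_factor_grid() if factor_grid is None
                         else factor_grid, dtype=float)
    dose = dose or DoseCondition(dose_uM=1.0)
    base_on, base_off = _response_times(params, dose, horizon, solver)
    names = FITTED_PARAMETER_NAMES
    shape = (len(names), len(factors))
    on_t, off_t = np.empty(shape), np.empty(shape)
    on_c = np.zeros(shape, dtype=bool)
    off_c = np.zeros(shape, dtype=bool)
    for i, name in enumerate(names):
        for j, f in enumerate(factors):
            if f == 1.0:
                on, off = base_on, base_off
            else:
                perturbed = replace(params, **{name: getattr(params, name) * f})
                try:
                    on, off = _response_times(perturbed, dose, horizon, solver)
                except SimulationError:
                    on_t[i, j] = off_t[i, j] = horizon
                    on_c[i, j] = off_c[i, j] = True
                    continue
            on_t[i, j], on_c[i, j] = on.value, on.censored
            off_t[i, j], off_c[i, j] = off.value, off.censored
    return SensitivityTable(names, factors, on_t, off_t, on_c, off_c,
                            base_on.value, base_off.value, horizon)


@dataclass(frozen=True)
class DoseResponseCurve:
    doses_uM: np.ndarray
    on_times: np.ndarray
    off_times: np.ndarray
    on_censored: np.ndarray
    off_censored: np.ndarray
    horizon: float

    def to_records(self) -> list[dict]:
        return [{
            "dose_uM": float(d),
            "on_response_time": float(self.on_times[i]),
            "off_response_time": float(self.off_times[i]),
            "on_censored": bool(self.on_censored[i]),
            "off_censored": bool(self.off_censored[i]),
        } for i, d in enumerate(self.doses_uM)]


def dose_response(params: ReducedParameters, dose_grid=None,
                  horizon: float = DEFAULT_HORIZON_DAYS,
                  dose_map: DoseCondition | None = None,
                  solver: SolverConfig | None = None) -> DoseResponseCurve:
    """Response time of both switches across a 4-OHT dose sweep.

    Each grid point is an independent simulation from the common initial
    state; no state carries over between doses.
    """
    doses = np.asarray(default_dose_grid() if dose_grid is None else dose_grid,
                       dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    dose_map = dose_map or DoseCondition(dose_uM=1.0)
    n = len(doses)
    on_t, off_t = np.empty(n), np.empty(n)
    on_c, off_c = np.zeros(n, dtype=bool), np.zeros(n, dtype=bool)
    for i, d in enumerate(doses):
        on, off = _response_times(params, dose_map.at_dose(float(d)), horizon,
                                  solver)
        on_t[i], on_c[i] = on.value, on.censored
        off_t[i], off_c[i] = off.value, off.censored
    return DoseResponseCurve(doses, on_t, off_t, on_c, off_c, horizon)


def fold_change_scan(params: ReducedParameters,
                     folds: Sequence[float] = (1.0, 2.0, 5.0),
                     doses_uM: Sequence[float] = (0.0, 1.0),
                     horizon: float = DEFAULT_HORIZON_DAYS,
                     dose_map: DoseCondition | None = None,
                     solver: SolverConfig | None = None,
                     n_grid: int = 501) -> dict:
    """Full ON/OFF time courses under joint alpha_a/alpha_b fold changes.

    Returns ``{"t": grid, (fold, dose_uM, orientation): percent series}``.
    """
    if any(f <= 0 for f in folds):
        raise ValueError("folds must be > 0")
    dose_map = dose_map or DoseCondition(dose_uM=1.0)
    t_grid = np.linspace(0.0, horizon, n_grid)
    out: dict = {"t": t_grid}
    for f in folds:
        scaled = replace(params, alpha_a=params.alpha_a * f,
                         alpha_b=params.alpha_b * f)
        for d in doses_uM:
            traj = simulate("reduced", scaled, dose_map.at_dose(float(d)),
                            t_grid, solver)
            for orientation in ("ON", "OFF"):
                out[(float(f), float(d), orientation)] = percent_car(
                    traj, orientation)
    return out


@dataclass(frozen=True)
class TradeoffGrid:
    """Response-time matrices over (expression fold x dose)."""

    folds: np.ndarray
    doses_uM: np.ndarray
    on_times: np.ndarray       # (n_folds, n_doses)
    off_times: np.ndarray
    on_censored: np.ndarray
    off_censored: np.ndarray
    horizon: float

    def to_records(self) -> list[dict]:
        rows = []
        for i, f in enumerate(self.folds):
            for j, d in enumerate(self.doses_uM):
                rows.append({
                    "fold": float(f), "dose_uM": float(d),
                    "on_response_time": float(self.on_times[i, j]),
                    "off_response_time": float(self.off_times[i, j]),
                    "on_censored": bool(self.on_censored[i, j]),
                    "off_censored": bool(self.off_censored[i, j]),
                })
        return rows


def tradeoff_grid(params: ReducedParameters, fold_grid=None, dose_grid=None,
                  horizon: float = DEFAULT_HORIZON_DAYS,
                  dose_map: DoseCondition | None = None,
                  solver: SolverConfig | None = None) -> TradeoffGrid:
    """Cross joint FlpO-expression fold changes with the 4-OHT dose sweep.

    The default fold grid spans one order of magnitude either side of the
    baseline.  The fold-1 row reproduces :func:`dose_response` exactly (same
    code path per cell).
    """
    folds = np.asarray(np.logspace(-1.0, 1.0, 9) if fold_grid is None
                       else fold_grid, dtype=float)
    doses = np.asarray(default_dose_grid() if dose_grid is None else dose_grid,
                       dtype=float)
    if folds.size == 0 or doses.size == 0:
        raise ValueError("fold and dose grids must be non-empty")
    shape = (len(folds), len(doses))
    on_t, off_t = np.empty(shape), np.empty(shape)
    on_c = np.zeros(shape, dtype=bool)
    off_c = np.zeros(shape, dtype=bool)
    for i, f in enumerate(folds):
        scaled = replace(params, alpha_a=params.alpha_a * float(f),
                         alpha_b=params.alpha_b * float(f))
        curve = dose_response(scaled, doses, horizon, dose_map, solver)
        on_t[i], off_t[i] = curve.on_times, curve.off_times
        on_c[i], off_c[i] = curve.on_censored, curve.off_censored
    return TradeoffGrid(folds, doses, on_t, off_t, on_c, off_c, horizon)
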