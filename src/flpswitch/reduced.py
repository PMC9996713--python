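"""Reduced mass-action model of the inversion-excision switch.

The full mechanistic network (:mod:`flpswitch.mechanistic`) collapses, after
removing the low-sensitivity Holliday-junction and cooperative-binding detail,
to nine coupled ODEs: four protein/drug species (active nuclear FlpO ``F``,
inducer ``OHT``, inactive cytosolic FlpO ``Fa``, leak-pathway FlpO ``Fb``) and
five DNA states (initial ``D_S1``, the two CAR-expressing transient inversion
states ``D_tS1``/``D_tS2``, the excised loop ``D_SX`` and the final excised
state ``D_S2``).  Each of the four recombination events is a single reversible
reaction; all four reverse reactions share one rate constant ``k_r``.

Twelve rate constants are fitted (all on [0, 1]); the 4-OHT source rate
``alpha_d`` is a dose-derived input and the cytoplasm-to-nucleus volume
quotient ``vbar`` is fixed at 0.3, so neither is fitted.

Units: concentrations in arbitrary units (a.u.), time in days, first-order
rates in 1/day, second-order rates in 1/(a.u.*day).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "ReducedParameters",
    "ReducedState",
    "STATE_NAMES",
    "FITTED_PARAMETER_NAMES",
    "reduced_rhs",
    "reduced_rhs_vector",
    "reduced_initial_state",
]

#: integration order of the nine state variables
STATE_NAMES = ("F", "OHT", "Fa", "Fb", "D_S1", "D_tS1", "D_tS2", "D_SX", "D_S2")

#: the 12 rate constants subject to inference (search box [0, 1] each)
FITTED_PARAMETER_NAMES = (
    "alpha_a", "alpha_b", "beta_p", "beta_d", "K_a", "K_b",
    "k1", "k2", "k3", "k4", "k_r", "delta",
)

VBAR_DEFAULT = 0.3


@dataclass(frozen=True)
class ReducedParameters:
    """Rate constants of the reduced model.

    ``k1``/``k2`` are the forward inversion rates S1 -> tS1 and S1 -> tS2;
    ``k3``/``k4`` the forward excision rates tS1 -> S2 + SX and
    tS2 -> S2 + SX; ``k_r`` the shared reverse-recombination rate and
    ``delta`` the dilution rate of the free excised loop.
    """

    alpha_a: float
    alpha_b: float
    beta_p: float
    beta_d: float
    K_a: float
    K_b: float
    k1: float
    k2: float
    k3: float
    k4: float
    k_r: float
    delta: float
    alpha_d: float = 0.0
    vbar: float = VBAR_DEFAULT

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name}={v!r} must be finite and >= 0")

    def fitted_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FITTED_PARAMETER_NAMES])

    @classmethod
    def from_fitted_vector(
        cls, theta, alpha_d: float = 0.0, vbar: float = VBAR_DEFAULT
    ) -> "ReducedParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(FITTED_PARAMETER_NAMES),):
            raise ValueError(f"expected {len(FITTED_PARAMETER_NAMES)} fitted values")
        kw = dict(zip(FITTED_PARAMETER_NAMES, theta.tolist()))
        return cls(alpha_d=alpha_d, vbar=vbar, **kw)

    def with_dose_rate(self, alpha_d: float) -> "ReducedParameters":
        return replace(self, alpha_d=alpha_d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ReducedState:
    """One point of the reduced state space (all concentrations in a.u.)."""

    F: float = 0.0
    OHT: float = 0.0
    Fa: float = 0.0
    Fb: float = 0.0
    D_S1: float = 0.0
    D_tS1: float = 0.0
    D_tS2: float = 0.0
    D_SX: float = 0.0
    D_S2: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES])

    @classmethod
    def from_vector(cls, y) -> "ReducedState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ValueError(f"expected a length-{len(STATE_NAMES)} state vector")
        return cls(**dict(zip(STATE_NAMES, y.tolist())))

    @property
    def genomic_total(self) -> float:
        """Total chromosomal DNA D_S1 + D_tS1 + D_tS2 + D_S2 (conserved)."""
        return self.D_S1 + self.D_tS1 + self.D_tS2 + self.D_S2


def reduced_initial_state(dose_au: float, total_dna: float = 1.0) -> ReducedState:
    """Initial condition: all DNA in State 1, no FlpO, inducer at ``dose_au``."""
    if dose_au < 0:
        raise ValueError("dose_au must be >= 0")
    if total_dna <= 0:
        raise ValueError("total_dna must be > 0")
    return ReducedState(OHT=dose_au, D_S1=total_dna)


def reduced_rhs_vector(y, p: ReducedParameters):
    """Time derivative of the raw state vector (fast path for the solvers).

    Accepts and returns a plain sequence ordered as :data:`STATE_NAMES`.
    """
    F, OHT, Fa, Fb, S1, T1, T2, SX, S2 = y
    act = p.K_a * OHT * Fa          # 4-OHT-dependent activation flux (no vbar)
    leak = p.K_b * Fb               # leaky nuclear-localisation flux (no vbar)
    fS1_1 = p.k1 * F * S1           # forward inversion S1 -> tS1
    fS1_2 = p.k2 * F * S1           # forward inversion S1 -> tS2
    rT1 = p.k_r * F * T1            # reverse inversion tS1 -> S1
    rT2 = p.k_r * F * T2            # reverse inversion tS2 -> S1
    fX1 = p.k3 * F * T1             # forward excision tS1 -> S2 + SX
    fX2 = p.k4 * F * T2             # forward excision tS2 -> S2 + SX
    rX = p.k_r * SX * S2            # reverse excision (no F involved)
    dF = (p.vbar * act + p.vbar * leak - p.beta_p * F
          - fS1_1 - rT1 - fS1_2 - rT2 - fX1 - fX2)
    dOHT = p.alpha_d - p.beta_d * OHT - act
    dFa = p.alpha_a - p.beta_p * Fa - act
    dFb = p.alpha_b - p.beta_p * Fb - leak
    dS1 = rT1 - fS1_1 + rT2 - fS1_2
    dT1 = fS1_1 - rT1 - fX1 + rX
    dT2 = fS1_2 - rT2 - fX2 + rX
    dSX = fX1 + fX2 - 2.0 * rX - p.delta * SX
    dS2 = fX1 + fX2 - 2.0 * rX
    return (dF, dOHT, dFa, dFb, dS1, dT1, dT2, dSX, dS2)


def reduced_rhs(state: ReducedState, params: ReducedParameters) -> ReducedState:
    """Typed wrapper around :func:`reduced_rhs_vector`."""
    dy = reduced_rhs_vector(state.to_vector(), params)
    return ReducedState(**dict(zip(STATE_NAMES, dy)))
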