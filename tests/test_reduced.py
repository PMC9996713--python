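"""Unit tests for the reduced nine-ODE switch model."""

import numpy as np
import pytest

from flpswitch import (DoseCondition, ReducedParameters, ReducedState,
                       reduced_initial_state, reduced_rhs, reduced_rhs_vector,
                       simulate)
from flpswitch.reduced import FITTED_PARAMETER_NAMES, STATE_NAMES


def rhs_oracle(state: dict, p: dict) -> dict:
    """Independent term-by-term transcription of the nine rate equations.

    Written directly from the printed equations, one line per equation, with
    no shared code with the implementation.
    """
    F, OHT, Fa, Fb = state["F"], state["OHT"], state["Fa"], state["Fb"]
    DS1, DtS1, DtS2 = state["D_S1"], state["D_tS1"], state["D_tS2"]
    DSX, DS2 = state["D_SX"], state["D_S2"]
    vb = p["vbar"]
    return {
        "F": (p["K_a"] * vb * OHT * Fa + p["K_b"] * vb * Fb - p["beta_p"] * F
              - p["k1"] * F * DS1 - p["k_r"] * F * DtS1 - p["k2"] * F * DS1
              - p["k_r"] * F * DtS2 - p["k3"] * F * DtS1 - p["k4"] * F * DtS2),
        "OHT": p["alpha_d"] - p["beta_d"] * OHT - p["K_a"] * OHT * Fa,
        "Fa": p["alpha_a"] - p["beta_p"] * Fa - p["K_a"] * OHT * Fa,
        "Fb": p["alpha_b"] - p["beta_p"] * Fb - p["K_b"] * Fb,
        "D_S1": (p["k_r"] * F * DtS1 - p["k1"] * F * DS1
                 + p["k_r"] * F * DtS2 - p["k2"] * F * DS1),
        "D_tS1": (p["k1"] * F * DS1 - p["k_r"] * F * DtS1
                  - p["k3"] * F * DtS1 + p["k_r"] * DSX * DS2),
        "D_tS2": (p["k2"] * F * DS1 - p["k_r"] * F * DtS2
                  - p["k4"] * F * DtS2 + p["k_r"] * DSX * DS2),
        "D_SX": (p["k3"] * F * DtS1 - p["k_r"] * DSX * DS2
                 + p["k4"] * F * DtS2 - p["k_r"] * DSX * DS2
                 - p["delta"] * DSX),
        "D_S2": (p["k3"] * F * DtS1 - p["k_r"] * DSX * DS2
                 + p["k4"] * F * DtS2 - p["k_r"] * DSX * DS2),
    }


def random_params(rng) -> ReducedParameters:
    theta = rng.uniform(0.0, 1.0, len(FITTED_PARAMETER_NAMES))
    return ReducedParameters.from_fitted_vector(theta, alpha_d=rng.uniform(0, 2))


def test_rhs_matches_independent_oracle(rng):
    for _ in range(25):
        p = random_params(rng)
        y = rng.uniform(0.0, 3.0, 9)
        expected = rhs_oracle(dict(zip(STATE_NAMES, y)), p.to_dict())
        got = reduced_rhs_vector(y, p)
        np.testing.assert_allclose(
            got, [expected[n] for n in STATE_NAMES], rtol=1e-12)


def test_genomic_derivative_cancels_exactly(rng):
    for _ in range(50):
        p = random_params(rng)
        y = rng.uniform(0.0, 3.0, 9)
        d = reduced_rhs_vector(y, p)
        total = d[4] + d[5] + d[6] + d[8]  # D_S1 + D_tS1 + D_tS2 + D_S2
        assert total == pytest.approx(0.0, abs=1e-14)


def test_dna_frozen_without_flpo_and_loop(rng):
    p = random_params(rng)
    state = ReducedState(F=0.0, OHT=0.7, Fa=0.4, Fb=0.2, D_S1=1.0,
                         D_tS1=0.1, D_tS2=0.2, D_SX=0.0, D_S2=0.3)
    d = reduced_rhs(state, p)
    assert d.D_S1 == d.D_tS1 == d.D_tS2 == d.D_SX == d.D_S2 == 0.0
    assert d.Fa == pytest.approx(
        p.alpha_a - p.beta_p * state.Fa - p.K_a * state.OHT * state.Fa)


def test_typed_rhs_agrees_with_vector_path(rng):
    p = random_params(rng)
    y = rng.uniform(0.0, 2.0, 9)
    typed = reduced_rhs(ReducedState.from_vector(y), p)
    np.testing.assert_allclose(typed.to_vector(), reduced_rhs_vector(y, p))


@pytest.mark.parametrize("dose, dna", [(0.0, 1.0), (0.5, 1.0), (2.0, 0.25)])
def test_initial_state_definition(dose, dna):
    s = reduced_initial_state(dose, dna)
    assert s.D_S1 == dna and s.OHT == dose
    assert s.F == s.Fa == s.Fb == s.D_tS1 == s.D_tS2 == s.D_SX == s.D_S2 == 0.0
    assert s.genomic_total == dna


def test_initial_state_rejects_bad_inputs():
    with pytest.raises(ValueError):
        reduced_initial_state(-0.1)
    with pytest.raises(ValueError):
        reduced_initial_state(0.0, total_dna=0.0)


def test_parameters_reject_negative_values():
    with pytest.raises(ValueError):
        ReducedParameters(alpha_a=-0.1, alpha_b=0.1, beta_p=0.1, beta_d=0.1,
                          K_a=0.1, K_b=0.1, k1=0.1, k2=0.1, k3=0.1, k4=0.1,
                          k_r=0.1, delta=0.1)


def test_fitted_vector_roundtrip(rng):
    p = random_params(rng)
    q = ReducedParameters.from_fitted_vector(p.fitted_vector(), alpha_d=p.alpha_d)
    assert q == p
    assert len(FITTED_PARAMETER_NAMES) == 12


def test_zero_induction_zero_leak_freezes_dna(truth):
    from dataclasses import replace
    p = replace(truth, alpha_b=0.0, K_b=0.0, alpha_d=0.0)
    traj = simulate("reduced", p, DoseCondition(0.0), np.linspace(0, 10, 41))
    np.testing.assert_allclose(traj.series("D_S1"), 1.0, atol=1e-9)
    assert np.all(np.abs(traj.series("F")) < 1e-12)


def test_excised_loop_decays_without_reverse_flux(truth):
    # delta > 0, k_r = 0 and no further influx: D_SX is non-increasing
    from dataclasses import replace
    p = replace(truth, k_r=0.0, alpha_a=0.0, alpha_b=0.0, alpha_d=0.0)
    t = np.linspace(0, 10, 51)
    y0 = np.array([0, 0, 0, 0, 0.2, 0.1, 0.1, 0.5, 0.1])
    from scipy.integrate import odeint
    out = odeint(lambda y, _t: reduced_rhs_vector(y, p), y0, t,
                 rtol=1e-9, atol=1e-12)
    sx = out[:, 7]
    assert np.all(np.diff(sx) <= 1e-12)
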