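"""Structural and numerical tests for the full mechanistic network."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flpswitch import (DoseCondition, effective_binding_rates,
                       mass_action_rhs, mechanistic_initial_state, simulate,
                       state_totals)
from flpswitch.mechanistic import FITTED_MECHANISTIC_NAMES, HJ_TAGS


# --- cooperative binding -----------------------------------------------------

def test_effective_binding_rates_worked_example():
    free, occ = effective_binding_rates(1.0, 1.0, 0.5, 0.5)
    assert free == (0.5, 1.0)
    assert occ == (1.0, 0.5)
    assert free[0] / free[1] < occ[0] / occ[1]


def test_multipliers_near_one_recover_noncooperative_limit():
    free, occ = effective_binding_rates(0.7, 0.3, 1 - 1e-12, 1 - 1e-12)
    np.testing.assert_allclose(free, occ, rtol=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(k_on=st.floats(1e-6, 10), k_off=st.floats(1e-6, 10),
       m1=st.floats(1e-6, 1, exclude_max=True),
       m2=st.floats(1e-6, 1, exclude_max=True))
def test_cooperativity_inequality_always_holds(k_on, k_off, m1, m2):
    (on_f, off_f), (on_o, off_o) = effective_binding_rates(k_on, k_off, m1, m2)
    assert on_f / off_f < on_o / off_o


@pytest.mark.parametrize("m1, m2", [(0.0, 0.5), (1.0, 0.5), (0.5, 1.2)])
def test_multiplier_constraint_violations_rejected(m1, m2):
    with pytest.raises(ValueError):
        effective_binding_rates(1.0, 1.0, m1, m2)


# --- structure ---------------------------------------------------------------

def test_structural_counts(network):
    dna = network.dna_species
    assert len(dna) == 63
    assert network.n_species - len(dna) == 4
    assert network.fitted_parameter_names == set(FITTED_MECHANISTIC_NAMES)
    assert len(FITTED_MECHANISTIC_NAMES) == 27


def test_species_identity_triples_unique(network):
    triples = {(s.pathway, s.state_tag, s.occupancy) for s in network.species}
    assert len(triples) == network.n_species


def test_network_splits_into_four_recombination_pathways(network):
    pathways = {s.pathway for s in network.species if s.pathway}
    assert pathways == {"i1", "i2", "e1", "e2"}
    for path in pathways:
        hj = [s for s in network.species
              if s.pathway == path and s.state_tag in HJ_TAGS]
        assert len(hj) == 5


def test_reactions_at_most_bimolecular_and_conserve_strands(network):
    S = network.stoichiometry_matrix
    pmask = network.promoter_strand_mask()
    bmask = network.blank_unit_mask()
    assert np.all(np.abs(pmask @ S) < 1e-12)  # promoter strand conserved
    blank_change = bmask @ S
    violators = [network.reactions[j].name
                 for j in np.nonzero(np.abs(blank_change) > 1e-12)[0]]
    assert violators == ["dilution:SX->"]  # only the loop-dilution sink
    for rxn in network.reactions:
        assert sum(n for _, n in rxn.reactants) <= 2


def test_monomer_delta_bookkeeping(network):
    binding = next(r for r in network.reactions if r.name == "i1:free+F->F1")
    unbinding = next(r for r in network.reactions if r.name == "i1:F1->free+F")
    assert binding.monomer_delta == -1
    assert unbinding.monomer_delta == 1


def test_json_export_is_complete(network):
    doc = json.loads(network.to_json())
    assert len(doc["species"]) == 67
    assert len(doc["reactions"]) == len(network.reactions)
    assert all(r["rate_ref"] in doc["rate_values"] for r in doc["reactions"])


# --- mass-action RHS ---------------------------------------------------------

def naive_rhs(network, state):
    """Per-reaction brute-force accumulation, no stoichiometry matrix."""
    dy = np.zeros(network.n_species)
    for rxn in network.reactions:
        flux = network.rate_values[rxn.rate_ref]
        for name, order in rxn.reactants:
            flux *= state[network.index[name]] ** order
        for name, order in rxn.reactants:
            dy[network.index[name]] -= order * flux
        for name, order in rxn.products:
            dy[network.index[name]] += order * flux
    return dy


def test_rhs_equals_naive_per_reaction_oracle(network, rng):
    for _ in range(100):
        y = rng.uniform(0.0, 2.0, network.n_species)
        np.testing.assert_allclose(mass_action_rhs(network, y),
                                   naive_rhs(network, y), rtol=1e-10,
                                   atol=1e-12)


def test_zero_state_leaves_only_source_terms(network, mech_params):
    d = mass_action_rhs(network, np.zeros(network.n_species))
    nonzero = {network.species[i].name: v for i, v in enumerate(d) if v != 0.0}
    assert nonzero == {"Fa": mech_params.alpha_a, "Fb": mech_params.alpha_b,
                       "OHT": mech_params.alpha_d}


def test_rhs_rejects_wrong_dimension(network):
    with pytest.raises(ValueError):
        mass_action_rhs(network, np.zeros(5))


# --- aggregation and conservation along trajectories -------------------------

def test_state_totals_initial_condition(network):
    y = mechanistic_initial_state(network, dose_au=0.0, total_dna=2.0)
    s1, expressing = state_totals(network, y)
    assert s1 == 2.0 and expressing == 0.0


def test_excision_products_count_half_each(network):
    y = np.zeros(network.n_species)
    y[network.index["e1.S2.F2"]] = 1.0
    y[network.index["e1.SX.F2"]] = 1.0
    s1, expressing = state_totals(network, y)
    assert expressing == pytest.approx(1.0)  # one excised parental DNA
    assert s1 == 0.0


def test_state_totals_weight_override(network):
    y = np.zeros(network.n_species)
    y[network.index["S2"]] = 1.0
    _, default = state_totals(network, y)
    _, overridden = state_totals(network, y, weights={"S2": 1.0})
    assert default == pytest.approx(0.5) and overridden == pytest.approx(1.0)


@pytest.fixture(scope="module")
def mech_traj(mech_params):
    t = np.linspace(0.0, 10.0, 201)
    return simulate("mechanistic", mech_params, DoseCondition(1.0), t)


def test_promoter_strand_total_constant_on_trajectory(mech_traj, network):
    pmask = network.promoter_strand_mask()
    totals = mech_traj.y @ pmask
    np.testing.assert_allclose(totals, totals[0], rtol=1e-6)


def test_trajectory_stays_nonnegative(mech_traj):
    assert mech_traj.y.min() > -1e-8


def test_blank_unit_flux_equals_loop_dilution(mech_traj, network, mech_params):
    bmask = network.blank_unit_mask()
    t, y = mech_traj.t, mech_traj.y
    totals = y @ bmask
    dt = t[1] - t[0]
    deriv = (totals[2:] - totals[:-2]) / (2 * dt)
    sx = y[1:-1, network.index["SX"]]
    np.testing.assert_allclose(deriv, -mech_params.delta * sx,
                               rtol=1e-3, atol=1e-9)


def test_state1_group_flux_matches_inversion_boundary(mech_traj, network,
                                                      mech_params):
    """d/dt of the State-1 aggregate equals the junction-boundary flux.

    The only reactions crossing the State-1 group boundary are the
    inversion-product F4 complexes entering the Holliday ladder (rate k3) and
    HJ5 exiting to the product side (rate k-3); the aggregate's finite
    difference must reproduce k3*(tS-side F4) - k-3*(HJ5 terms).
    """
    t, y = mech_traj.t, mech_traj.y
    totals = np.array([state_totals(network, row)[0] for row in y])
    dt = t[1] - t[0]
    deriv = (totals[2:] - totals[:-2]) / (2 * dt)
    mid = y[1:-1]
    flux = (mech_params.k3 * (mid[:, network.index["i1.tS1.F4"]]
                              + mid[:, network.index["i2.tS2.F4"]])
            - mech_params.k3_rev * (mid[:, network.index["i1.HJ5.F4"]]
                                    + mid[:, network.index["i2.HJ5.F4"]]))
    np.testing.assert_allclose(deriv, flux, rtol=2e-3, atol=1e-8)
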