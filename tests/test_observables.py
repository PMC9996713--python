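"""Observable definitions: percent CAR, response time, normalization, dosing."""

from dataclasses import replace

import numpy as np
import pytest

from flpswitch import (DoseCondition, SolverConfig, TimeCourseDataset,
                       Trajectory, normalize_to_global_max, percent_car,
                       response_time, simulate)
from flpswitch.reduced import STATE_NAMES


def reduced_traj(rows):
    """Build a reduced-model trajectory from explicit state rows."""
    t = np.arange(len(rows), dtype=float)
    return Trajectory(t, np.asarray(rows, dtype=float), "reduced", STATE_NAMES)


def state(D_S1=0.0, D_tS1=0.0, D_tS2=0.0, D_SX=0.0, D_S2=0.0):
    return [0.0, 0.0, 0.0, 0.0, D_S1, D_tS1, D_tS2, D_SX, D_S2]


def test_percent_car_definitions():
    traj = reduced_traj([state(D_S1=1.0), state(D_S1=1.0)])
    np.testing.assert_allclose(percent_car(traj, "ON"), 0.0)
    np.testing.assert_allclose(percent_car(traj, "OFF"), 100.0)
    quarters = reduced_traj([state(D_S1=0.25, D_tS1=0.25, D_tS2=0.25,
                                   D_S2=0.25)] * 2)
    np.testing.assert_allclose(percent_car(quarters, "ON"), 75.0)


def test_on_off_split_is_an_identity(rng):
    rows = [state(*rng.uniform(0.01, 1.0, 5)) for _ in range(6)]
    traj = reduced_traj(rows)
    on, off = percent_car(traj, "ON"), percent_car(traj, "OFF")
    arr = np.asarray(rows)
    transient = 100.0 * (arr[:, 5] + arr[:, 6]) / (
        arr[:, 4] + arr[:, 5] + arr[:, 6] + arr[:, 8])
    # ON% counts transients and State 2; OFF% counts State 1 of the mirrored
    # construct, so ON = 100 - OFF holds exactly (transients express in both)
    np.testing.assert_allclose(on + off, 100.0, rtol=1e-12)
    assert np.all(transient >= 0)


def test_percent_car_rejects_zero_genome():
    traj = reduced_traj([state()])
    with pytest.raises(ValueError):
        percent_car(traj, "ON")
    with pytest.raises(ValueError):
        percent_car(reduced_traj([state(D_S1=1.0)]), "sideways")


# --- response time -----------------------------------------------------------

def test_linear_rise_crosses_ninety_at_nine_days():
    t = np.linspace(0, 10, 1001)
    rt = response_time(t, 10.0 * t, "ON")
    assert not rt.censored
    assert rt.value == pytest.approx(9.0, abs=1e-9)


def test_constant_positive_series_has_zero_response_time():
    t = np.linspace(0, 10, 11)
    rt = response_time(t, np.full_like(t, 42.0), "ON")
    assert rt.value == 0.0 and not rt.censored


def test_flat_series_is_censored():
    t = np.linspace(0, 10, 11)
    assert response_time(t, np.zeros_like(t), "ON").censored
    assert response_time(t, np.full_like(t, 100.0), "OFF").censored


def test_off_switch_ninety_percent_of_decrease():
    t = np.linspace(0, 10, 1001)
    series = 100.0 - 8.0 * t  # falls 100 -> 20; 90% of the drop at t = 9
    rt = response_time(t, series, "OFF")
    assert rt.value == pytest.approx(9.0, abs=1e-9)


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        response_time(np.array([]), np.array([]), "ON")


def test_interpolated_response_time_matches_dense_scan(truth):
    t = np.linspace(0.0, 10.0, 501)
    traj = simulate("reduced", truth, DoseCondition(1.0), t)
    on = percent_car(traj, "ON")
    coarse = response_time(t, on, "ON")
    t_fine = np.arange(0.0, 10.0 + 1e-9, 1e-4)
    fine = percent_car(simulate("reduced", truth, DoseCondition(1.0), t_fine),
                       "ON")
    target = 0.9 * fine.max()
    brute = t_fine[np.argmax(fine >= target)]
    assert abs(coarse.value - brute) < 1e-4 + (t[1] - t[0])


# --- normalization -----------------------------------------------------------

def make_datasets(values_list):
    days = np.arange(1.0, 11.0)
    keys = [("ON", 0.0), ("OFF", 0.0), ("ON", 1.0), ("OFF", 1.0)]
    return [TimeCourseDataset(o, d, days, v)
            for (o, d), v in zip(keys, values_list)]


def test_normalization_identity_and_scale_invariance(rng):
    vals = [rng.uniform(0, 80, 10) for _ in range(4)]
    vals[0][3] = 100.0
    ds = make_datasets(vals)
    out = normalize_to_global_max(ds)
    for a, b in zip(ds, out):
        np.testing.assert_allclose(a.percent_car, b.percent_car)
    halved = make_datasets([v / 2 for v in vals])
    out2 = normalize_to_global_max(halved)
    for a, b in zip(out, out2):
        np.testing.assert_allclose(a.percent_car, b.percent_car)


def test_normalized_global_max_is_exactly_100(rng):
    ds = make_datasets([rng.uniform(0, 37.5, 10) for _ in range(4)])
    out = normalize_to_global_max(ds)
    assert max(float(d.percent_car.max()) for d in out) == 100.0
    orders = [np.argsort(d.percent_car) for d in ds]
    for d, o in zip(out, orders):
        assert np.array_equal(np.argsort(d.percent_car), o)


def test_all_zero_normalization_rejected():
    ds = make_datasets([np.zeros(10)] * 4)
    with pytest.raises(ValueError):
        normalize_to_global_max(ds)


# --- simulation --------------------------------------------------------------

def test_frozen_limit_at_zero_dose(truth):
    p = replace(truth, alpha_b=0.0, K_b=0.0)
    traj = simulate("reduced", p, DoseCondition(0.0))
    np.testing.assert_allclose(traj.series("D_S1"), 1.0, atol=1e-9)


def test_genomic_total_conserved_over_ten_days(truth):
    traj = simulate("reduced", truth, DoseCondition(1.0))
    total = (traj.series("D_S1") + traj.series("D_tS1")
             + traj.series("D_tS2") + traj.series("D_S2"))
    np.testing.assert_allclose(total, total[0], rtol=1e-6)


def test_tightening_solver_tolerances_is_converged(truth):
    t = np.linspace(0, 10, 101)
    loose = simulate("reduced", truth, DoseCondition(1.0), t,
                     SolverConfig(rtol=1e-6, atol=1e-8))
    tight = simulate("reduced", truth, DoseCondition(1.0), t,
                     SolverConfig(rtol=5e-7, atol=5e-9))
    diff = np.abs(percent_car(loose, "ON") - percent_car(tight, "ON"))
    assert diff.max() < 0.1  # percentage points


def test_dose_condition_maps_linearly():
    dc = DoseCondition(2.0, alpha_d_at_1uM=0.5, oht0_at_1uM=0.25)
    assert dc.alpha_d == 1.0 and dc.oht0 == 0.5
    assert dc.at_dose(4.0).alpha_d == 2.0
    with pytest.raises(ValueError):
        DoseCondition(-1.0)


def test_unknown_model_rejected(truth):
    with pytest.raises(ValueError):
        simulate("hybrid", truth)
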