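"""Muscle torque generators: strength tables, torque law, activation lag."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from torquegait.mtg import (ActivationParams, activation_rate, build_mtg_set,
                            calibrate_tau_max, default_curves,
                            default_strength_table, flexion_from_extension,
                            mtg_torque, smoothed_activation_rate,
                            torso_strength_from_hips)


class TestStrengthTables:
    def test_torso_strength_is_hip_average(self):
        table = default_strength_table("pathological")
        ext, flex = torso_strength_from_hips(table)
        assert ext == pytest.approx(24.49, abs=0.01)
        assert flex == pytest.approx(17.19, abs=0.01)

    def test_torso_strength_symmetric_hips(self):
        table = default_strength_table("healthy")
        ext, _ = torso_strength_from_hips(table)
        assert ext == pytest.approx(48.82, abs=1e-12)

    @pytest.mark.parametrize("joint, tau_ext, expected", [
        ("ankle", 16.84, 5.85),    # weaker-side ankle pair
        ("hip", 18.64, 13.08),     # weaker-side hip pair
        ("knee", 24.55, 13.10),
    ])
    def test_flexion_from_extension_ratios(self, joint, tau_ext, expected):
        assert flexion_from_extension(tau_ext, joint) == pytest.approx(
            expected, abs=0.01)

    def test_identity_ratio_passthrough(self):
        # r = 1 would return the input unchanged; emulate via direct ratio
        assert flexion_from_extension(10.0, "hip") == pytest.approx(
            10.0 * 34.27 / 48.82, abs=1e-12)

    def test_ratio_consistent_across_populations(self):
        healthy = default_strength_table("healthy")
        path = default_strength_table("pathological")
        for joint in ("hip", "knee", "ankle"):
            r_h = (healthy.get(joint, "L", "flexion")
                   / healthy.get(joint, "L", "extension"))
            for side in ("L", "R"):
                r_p = (path.get(joint, side, "flexion")
                       / path.get(joint, side, "extension"))
                assert r_p == pytest.approx(r_h, abs=0.01)

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError):
            default_strength_table("unknown")


class TestTorqueLaw:
    def test_zero_activation_means_zero_torque(self, pathological_mtgs):
        for p in pathological_mtgs:
            assert mtg_torque(p, 0.0, 0.3, -1.0) == 0.0

    def test_normalization_at_peak(self, pathological_mtgs):
        for p in pathological_mtgs:
            tau = mtg_torque(p, 1.0, p.sign * p.theta_peak, 0.0)
            assert abs(tau) == pytest.approx(p.tau_max, rel=1e-12)

    def test_table_value_at_90_percent(self, pathological_mtgs):
        hip_ext_l = next(p for p in pathological_mtgs
                         if (p.joint, p.side, p.direction)
                         == ("hip", "L", "extension"))
        assert hip_ext_l.tau_max == pytest.approx(30.35)
        tau = mtg_torque(hip_ext_l, 0.9, hip_ext_l.sign * hip_ext_l.theta_peak, 0.0)
        assert abs(tau) == pytest.approx(27.315, abs=1e-9)

    def test_linearity_in_activation_and_strength(self, pathological_mtgs, rng):
        p = pathological_mtgs[3]
        theta, omega = 0.25, -0.8
        t1 = mtg_torque(p, 0.35, theta, omega)
        t2 = mtg_torque(p, 0.70, theta, omega)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_activation_out_of_range_rejected(self, pathological_mtgs):
        with pytest.raises(ValueError):
            mtg_torque(pathological_mtgs[0], 1.2, 0.0, 0.0)

    def test_velocity_curve_monotone_nonincreasing(self):
        _, fv = default_curves()
        omega = np.linspace(-12, 12, 400)
        vals = fv(omega)
        assert np.all(np.diff(vals) < 1e-6)
        assert fv(0.0) == pytest.approx(1.0, abs=1e-12)


class TestCalibration:
    def test_inverts_published_peak(self):
        assert calibrate_tau_max(0.0, 0.0, 27.315, a_assumed=0.9) == \
            pytest.approx(30.35, abs=1e-6)

    def test_identity_when_curves_are_unity(self):
        # at the curve peak with a = 1 the observed peak is the maximum
        assert calibrate_tau_max(0.0, 0.0, 12.5, a_assumed=1.0) == \
            pytest.approx(12.5, abs=1e-9)

    def test_round_trip_over_feasible_grid(self, pathological_mtgs):
        p = pathological_mtgs[0]
        for theta in np.linspace(-0.8, 0.8, 5):
            for omega in np.linspace(-6, 6, 5):
                tau_obs = mtg_torque(p, 0.9, p.sign * theta, p.sign * omega)
                est = calibrate_tau_max(theta, omega, abs(tau_obs),
                                        a_assumed=0.9,
                                        curves=(p.fA, p.fV))
                assert est == pytest.approx(p.tau_max, rel=1e-9)

    def test_rejects_infeasible_point(self):
        with pytest.raises(ValueError):
            calibrate_tau_max(0.0, 12.0, 10.0)   # fV vanishes at omega_max


class TestActivationDynamics:
    def test_fixed_point(self):
        assert activation_rate(0.5, 0.5) == 0.0

    def test_full_excitation_rate(self):
        assert activation_rate(1.0, 0.0) == pytest.approx(1 / 0.011, rel=1e-12)

    def test_deactivation_rate(self):
        assert activation_rate(0.0, 0.5) == pytest.approx(-0.5 / 0.068, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            activation_rate(1.5, 0.2)
        with pytest.raises(ValueError):
            activation_rate(0.5, -0.2)
        with pytest.raises(ValueError):
            ActivationParams(tau_A=0.1, tau_D=0.05)

    def test_deactivation_matches_closed_form(self):
        # constant e < a stays on the deactivation branch:
        # a(t) = e + (a0 - e) exp(-t / tau_D)
        e, a0, tau_D = 0.1, 0.9, 0.068
        sol = solve_ivp(lambda t, a: activation_rate(e, a[0]), [0, 0.3], [a0],
                        rtol=1e-11, atol=1e-13, dense_output=True)
        t = np.linspace(0, 0.3, 20)
        closed = e + (a0 - e) * np.exp(-t / tau_D)
        assert np.allclose(sol.sol(t)[0], closed, atol=1e-9)

    def test_monotone_convergence_to_constant_excitation(self):
        for e, a0 in ((0.8, 0.1), (0.2, 0.9)):
            sol = solve_ivp(lambda t, a: activation_rate(e, a[0]), [0, 1.0],
                            [a0], rtol=1e-9, max_step=0.01)
            traj = sol.y[0]
            diffs = np.diff(traj)
            assert np.all(diffs >= -1e-12) if e > a0 else np.all(diffs <= 1e-12)
            assert traj[-1] == pytest.approx(e, abs=1e-6)

    def test_bounds_preserved_under_random_excitations(self, rng):
        """1,000 random piecewise-constant excitation profiles keep a in
        [0, 1] (vectorized RK4 at a step well inside the stability bound)."""
        n = 1000
        a = rng.uniform(0, 1, n)
        dt = 0.002
        for _ in range(300):
            e = rng.uniform(0, 1, n)
            k1 = activation_rate(e, a)
            k2 = activation_rate(e, np.clip(a + dt / 2 * k1, 0, 1))
            k3 = activation_rate(e, np.clip(a + dt / 2 * k2, 0, 1))
            k4 = activation_rate(e, np.clip(a + dt * k3, 0, 1))
            a = a + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            assert np.all(a >= -1e-9) and np.all(a <= 1 + 1e-9)
            a = np.clip(a, 0, 1)

    def test_smoothed_variant_matches_exact_away_from_switch(self):
        assert smoothed_activation_rate(0.9, 0.2) == pytest.approx(
            activation_rate(0.9, 0.2), rel=1e-9)
        assert smoothed_activation_rate(0.1, 0.8) == pytest.approx(
            activation_rate(0.1, 0.8), rel=1e-9)


def test_mtg_set_has_14_actuators_with_canonical_pairs():
    mtgs = build_mtg_set()
    assert len(mtgs) == 14
    joints = {(p.joint, p.side) for p in mtgs}
    assert ("torso", None) in joints
    for p in mtgs:
        partner = [q for q in mtgs if (q.joint, q.side) == (p.joint, p.side)
                   and q.direction != p.direction]
        assert len(partner) == 1
        assert partner[0].sign == -p.sign


# -- property-based checks ---------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@settings(max_examples=200, derandomize=True)
@given(e=unit, a=unit)
def test_activation_rate_drives_toward_excitation(e, a):
    """The lag always moves the activation toward the excitation."""
    rate = activation_rate(e, a)
    assert rate * (e - a) >= 0.0
    smooth = smoothed_activation_rate(e, a)
    assert smooth * (e - a) >= -1e-9


@settings(max_examples=100, derandomize=True)
@given(a=unit, theta=st.floats(-1.5, 1.5), omega=st.floats(-10.0, 10.0))
def test_torque_bounded_by_eccentric_capacity(a, theta, omega):
    """MTG torque magnitude never exceeds the eccentric plateau times the
    maximum isometric torque."""
    from torquegait.mtg import ECCENTRIC_PLATEAU

    p = build_mtg_set()[2]   # a hip extensor
    tau = mtg_torque(p, a, theta, omega)
    assert abs(tau) <= ECCENTRIC_PLATEAU * p.tau_max * 1.01
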