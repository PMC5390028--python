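"""Ankle-foot orthosis torque-angle profile and mass bookkeeping."""

import numpy as np
import pytest

from torquegait.model import build_default_model
from torquegait.orthosis import (OrthosisParams, attach_orthosis,
                                 build_profile, default_orthosis_params,
                                 orthosis_torque)


@pytest.fixture(scope="module")
def left_profile():
    return build_profile(default_orthosis_params("L"))


def _secant_slope(profile, a, b, n=40):
    th = np.linspace(a, b, n)
    return np.polyfit(th, profile.torque(th), 1)[0]


class TestProfileShape:
    def test_preload_bounded_at_neutral_offset(self, left_profile):
        assert abs(orthosis_torque(left_profile, -0.02)) <= 1.0

    def test_torque_nonincreasing_in_angle(self, left_profile):
        th = np.linspace(-0.25, 0.2, 500)
        assert np.all(np.diff(left_profile.torque(th)) <= 1e-9)

    @pytest.mark.parametrize("side, region, expected", [
        ("L", (-0.11, -0.035), -55.0),   # dorsiflexion spring K_D
        ("L", (-0.005, 0.085), -5.0),    # plantarflexion spring K_P
        ("L", (-0.25, -0.125), -200.0),  # dorsiflexion hard stop K_DH
        ("L", (0.095, 0.25), -200.0),    # plantarflexion hard stop K_PH
        ("R", (-0.12, -0.035), -55.0),
        ("R", (-0.005, 0.095), -5.0),
    ])
    def test_stage_slopes_recovered_within_2_percent(self, side, region, expected):
        profile = build_profile(default_orthosis_params(side))
        slope = _secant_slope(profile, *region)
        assert slope == pytest.approx(expected, rel=0.02)

    def test_c2_at_all_junctions(self, left_profile):
        jumps = left_profile.curve.junction_jumps()
        # second-derivative jumps measured against the local curvature scale
        scale = max(1.0, np.abs(left_profile.curve(
            left_profile.curve.breakpoints[1:-1], deriv=2)).max())
        assert np.all(jumps[:, 2] / scale < 1e-6)

    def test_piecewise_law_in_spring_region(self, left_profile):
        # small step into the plantarflexion spring region past the window
        p = left_profile.params
        edge = p.theta_0 + p.theta_W
        for delta in (0.01, 0.03, 0.05):
            expected = -(p.tau_0 + p.K_P * delta)
            assert left_profile.torque(edge + delta) == pytest.approx(
                expected, abs=1e-9)

    def test_doubling_kp_doubles_incremental_torque(self):
        base = default_orthosis_params("L")
        p2 = OrthosisParams(**{**base.__dict__, "K_P": 2 * base.K_P})
        prof1, prof2 = build_profile(base), build_profile(p2)
        edge = base.theta_0 + base.theta_W
        theta = edge + 0.04
        inc1 = prof1.torque(theta) - prof1.torque(edge)
        inc2 = prof2.torque(theta) - prof2.torque(edge)
        assert inc2 == pytest.approx(2 * inc1, rel=1e-6)

    def test_affine_in_free_springs_over_grid(self, left_profile):
        th = np.linspace(-0.2, 0.15, 50)
        for kd, kp in ((10.0, 2.0), (80.0, 30.0)):
            direct = build_profile(
                OrthosisParams(**{**left_profile.params.__dict__,
                                  "K_D": kd, "K_P": kp}))
            assert np.allclose(left_profile.torque(th, K_D=kd, K_P=kp),
                               direct.torque(th), atol=1e-10)

    def test_rebuild_is_bit_identical(self):
        p = default_orthosis_params("R")
        c1 = build_profile(p).curve
        c2 = build_profile(p).curve
        assert np.array_equal(c1.control, c2.control)
        assert np.array_equal(c1.breakpoints, c2.breakpoints)

    def test_parameter_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            OrthosisParams(side="L", theta_DH=0.0, theta_0=-0.02)
        with pytest.raises(ValueError):
            OrthosisParams(side="L", K_D=-5.0)


class TestAttachment:
    def test_added_masses_totals(self, child_model):
        equipped = attach_orthosis(child_model,
                                   default_orthosis_params("L"),
                                   default_orthosis_params("R"))
        assert equipped.total_mass == pytest.approx(
            24.7 + 2 * (0.34 + 0.69), abs=1e-9)

    def test_zero_added_mass_leaves_model_unchanged(self, child_model):
        zero = default_orthosis_params("L", shank_added_mass=0.0,
                                       foot_added_mass=0.0)
        zero_r = default_orthosis_params("R", shank_added_mass=0.0,
                                         foot_added_mass=0.0)
        equipped = attach_orthosis(child_model, zero, zero_r)
        for name in child_model.segments:
            assert equipped.segment(name) == child_model.segment(name)

    def test_attachment_at_com_preserves_com_and_inertia(self, child_model):
        equipped = attach_orthosis(child_model,
                                   default_orthosis_params("L"),
                                   default_orthosis_params("R"))
        for name in ("shank_l", "foot_l"):
            assert equipped.segment(name).com_offset == pytest.approx(
                child_model.segment(name).com_offset)
            assert equipped.segment(name).inertia_com == pytest.approx(
                child_model.segment(name).inertia_com)

    def test_offset_attachment_shifts_com_and_adds_inertia(self, child_model):
        equipped = attach_orthosis(child_model,
                                   default_orthosis_params("L"),
                                   default_orthosis_params("R"),
                                   attachment_offsets={"shank_l": 0.0})
        seg0 = child_model.segment("shank_l")
        seg1 = equipped.segment("shank_l")
        assert seg1.com_offset < seg0.com_offset
        assert seg1.inertia_com > seg0.inertia_com

    def test_equipped_ankle_force_within_preload_in_window(self, child_model,
                                                           pathological_mtgs):
        """With zero activations and the ankle inside the preload window,
        the only ankle generalized force is the orthosis preload."""
        from torquegait.dynamics import DynamicsEngine

        params = {s: default_orthosis_params(s) for s in ("L", "R")}
        equipped = attach_orthosis(child_model, params["L"], params["R"])
        profiles = {s: build_profile(p) for s, p in params.items()}
        engine = DynamicsEngine(equipped, pathological_mtgs, profiles)
        q = np.zeros((10, 1))
        q[1] = 0.7
        q[6] = 0.02   # clinical -0.02: the torque-free offset
        q[9] = 0.02
        Q = engine.generalized_actuation(q, np.zeros((10, 1)),
                                         np.zeros((14, 1)))
        assert abs(float(Q[6, 0])) <= 1.0 + 1e-9
        assert abs(float(Q[9, 0])) <= 1.0 + 1e-9
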