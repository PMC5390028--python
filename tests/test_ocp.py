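"""Phase schedule, objective arithmetic and transcription structure."""

import numpy as np
import pytest

from torquegait.model import NDOF, NMUSCLES
from torquegait.ocp import (GUESS_PHASE_FRACTIONS, OCPConfig, ReferenceGait,
                            Solution, assemble_ocp, default_phase_schedule,
                            objective_ls, objective_mapd, objective_mapd_ws,
                            prototype_gait, prototype_reference)

NX = 2 * NDOF + NMUSCLES


def make_traj(times, q=None, act=None, controls=None, durations=None):
    times = np.asarray(times, dtype=float)
    n = times.size
    states = np.zeros((n, NX))
    if q is not None:
        states[:, :NDOF] = q
    if act is not None:
        states[:, 2 * NDOF:] = act
    u = np.zeros((n, NMUSCLES)) if controls is None else np.asarray(controls)
    if durations is None:
        durations = np.full(8, times[-1] / 8)
    return Solution(times=times, states=states, controls=u,
                    durations=np.asarray(durations, dtype=float))


class TestPhaseSchedule:
    def test_eight_phases(self):
        assert len(default_phase_schedule()) == 8

    def test_consecutive_sets_differ_by_one_event(self):
        phases = default_phase_schedule()
        for i, ph in enumerate(phases):
            prev = phases[i - 1]
            assert len(ph.contacts.active ^ prev.contacts.active) == 1

    def test_periodic_closure(self):
        phases = default_phase_schedule()
        # removing the left toe from the last phase yields the first set
        closing = set(phases[-1].contacts.active) - {"L_toe"}
        assert closing == set(phases[0].contacts.active)

    def test_entering_contacts_from_set_differences(self):
        phases = default_phase_schedule()
        expected = {3: ("L_heel",), 4: ("L_toe",), 7: ("R_heel",),
                    8: ("R_toe",)}
        for ph in phases:
            assert ph.entering == expected.get(ph.index, ())

    def test_flat_phases_have_heel_and_toe(self):
        phases = default_phase_schedule()
        assert phases[0].contacts.is_flat("R")
        assert phases[4].contacts.is_flat("L")


class TestTrackingObjective:
    def _ref(self, times, q, durations=None):
        durations = durations if durations is not None else np.full(8, times[-1] / 8)
        return ReferenceGait(times=np.asarray(times), q_meas=q,
                             durations=durations)

    def test_exact_fit_with_zero_controls_is_zero(self):
        times = np.linspace(0, 1, 9)
        q = np.outer(times, np.arange(NDOF))
        traj = make_traj(times, q=q)
        ref = self._ref(times[1:-1], q[1:-1])
        assert objective_ls(traj, ref) == 0.0

    def test_single_measurement_quadratic_form(self):
        times = np.linspace(0, 1, 5)
        q = np.zeros((5, NDOF))
        traj = make_traj(times, q=q)
        qm = np.zeros((1, NDOF))
        qm[0, 0] = -1.0          # error vector (1, 0, ..., 0)
        ref = self._ref([0.5], qm)
        assert objective_ls(traj, ref, delta=0.0) == pytest.approx(1.0)

    def test_control_regularization_closed_form(self):
        # constant u = 0.1 on all 14 controls over [0, 1]:
        # delta * 14 * 0.01 = 1.4e-5
        times = np.array([0.0, 1.0])
        traj = make_traj(times, controls=np.full((2, NMUSCLES), 0.1))
        ref = self._ref([0.5], np.zeros((1, NDOF)))
        val = objective_ls(traj, ref, delta=1e-4)
        assert val == pytest.approx(1e-4 * 14 * 0.01, abs=1e-14)

    def test_measurement_outside_support_rejected(self):
        traj = make_traj(np.linspace(0, 1, 5))
        ref = self._ref([1.5], np.zeros((1, NDOF)), durations=np.full(8, 0.25))
        with pytest.raises(ValueError):
            objective_ls(traj, ref)


class TestEffortObjectives:
    def test_zero_activation_zero_cost(self):
        times = np.linspace(0, 1, 5)
        q = np.zeros((5, NDOF))
        q[:, 0] = 0.5 * times
        traj = make_traj(times, q=q)
        assert objective_mapd(traj) == 0.0

    def test_constant_activation_closed_form(self):
        # a = 0.5 on 14 muscles for 1 s, 0.5 m travelled: 14*0.25/0.5 = 7
        times = np.linspace(0, 1, 9)
        q = np.zeros((9, NDOF))
        q[:, 0] = 0.5 * times
        traj = make_traj(times, q=q, act=np.full((9, NMUSCLES), 0.5))
        assert objective_mapd(traj) == pytest.approx(7.0, abs=1e-10)

    def test_distance_homogeneity(self):
        times = np.linspace(0, 1, 9)
        act = np.full((9, NMUSCLES), 0.3)
        q1 = np.zeros((9, NDOF)); q1[:, 0] = 0.4 * times
        q2 = np.zeros((9, NDOF)); q2[:, 0] = 0.8 * times
        v1 = objective_mapd(make_traj(times, q=q1, act=act))
        v2 = objective_mapd(make_traj(times, q=q2, act=act))
        assert v1 == pytest.approx(2 * v2, rel=1e-12)

    def test_no_forward_motion_rejected(self):
        traj = make_traj(np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            objective_mapd(traj)

    def test_walking_speed_term(self):
        # zero activations, r(T) = 0.77 m over T = 1 s, lambda = 2: -1.54
        times = np.linspace(0, 1, 5)
        q = np.zeros((5, NDOF))
        q[:, 0] = 0.77 * times
        traj = make_traj(times, q=q)
        assert objective_mapd_ws(traj, lam=2.0) == pytest.approx(-1.54, abs=1e-12)
        assert objective_mapd_ws(traj, lam=0.0) == objective_mapd(traj)

    def test_speed_term_monotone_in_speed(self):
        times = np.linspace(0, 1, 5)
        act = np.full((5, NMUSCLES), 0.2)
        vals = []
        for speed in (0.3, 0.5, 0.9):
            q = np.zeros((5, NDOF))
            q[:, 0] = speed * times
            vals.append(objective_mapd_ws(make_traj(times, q=q, act=act)))
        assert vals[0] > vals[1] > vals[2]


class TestTranscriptionStructure:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            OCPConfig(mode="LS")            # needs fixed durations
        with pytest.raises(ValueError):
            OCPConfig(n_shooting=10)        # not a multiple of 8
        with pytest.raises(ValueError):
            OCPConfig(mode="other")

    def test_ls_mode_fixed_durations_no_periodicity(self, child_model,
                                                    pathological_mtgs):
        ref = prototype_reference(child_model, OCPConfig(n_shooting=8))
        cfg = OCPConfig(mode="LS", n_shooting=8, fixed_durations=ref.durations)
        ocp = assemble_ocp(child_model, pathological_mtgs, None,
                           default_phase_schedule(), cfg, reference=ref)
        assert not ocp.periodic
        assert ocp.nd == 0
        # defects + entry rows only
        n_entry = len(ocp.entry_rows)
        assert ocp.eq_rows == 8 * NX + n_entry

    def test_mapd_constraint_count_audit(self, child_model, pathological_mtgs):
        """Equality row count equals the closed-form enumeration: one
        defect block per interval, the entering-contact rows implied by the
        schedule, initial anchoring and periodicity."""
        cfg = OCPConfig(mode="MAPD", n_shooting=16)
        ocp = assemble_ocp(child_model, pathological_mtgs, None,
                           default_phase_schedule(), cfg)
        # entering contacts: heel strikes contribute 3 rows (z, vz, vx),
        # toe-downs 2 (z, vz); initial set {R_heel, R_toe}: 3 + 2
        expected_entry = (3 + 2 + 3 + 2) + (3 + 2)
        assert len(ocp.entry_rows) == expected_entry
        assert ocp.eq_rows == 16 * NX + expected_entry + (NX - 1) + NMUSCLES
        assert ocp.nd == 8
        eq, _, _, _ = ocp._evaluate(ocp.default_guess())
        assert eq.shape == (ocp.eq_rows,)

    def test_free_stiffness_adds_four_parameters(self, child_model,
                                                 pathological_mtgs):
        from torquegait.orthosis import build_profile, default_orthosis_params

        profiles = {s: build_profile(default_orthosis_params(s))
                    for s in ("L", "R")}
        cfg0 = OCPConfig(mode="MAPD", n_shooting=8)
        cfg1 = OCPConfig(mode="MAPD", n_shooting=8, free_stiffness=True)
        ocp0 = assemble_ocp(child_model, pathological_mtgs, profiles,
                            default_phase_schedule(), cfg0)
        ocp1 = assemble_ocp(child_model, pathological_mtgs, profiles,
                            default_phase_schedule(), cfg1)
        assert ocp1.nvar - ocp0.nvar == 4
        with pytest.raises(ValueError):
            assemble_ocp(child_model, pathological_mtgs, None,
                         default_phase_schedule(), cfg1)

    def test_objective_gradient_and_hessian_consistency(self, child_model,
                                                        pathological_mtgs, rng):
        cfg = OCPConfig(mode="MAPD_WS", n_shooting=8)
        ocp = assemble_ocp(child_model, pathological_mtgs, None,
                           default_phase_schedule(), cfg)
        z = ocp.default_guess()
        z += rng.normal(0, 1e-3, z.size)
        g = ocp.objective_grad(z)
        H = ocp.objective_hess(z).toarray()
        h = 1e-6
        for c in rng.choice(ocp.nvar, 6, replace=False):
            zp, zm = z.copy(), z.copy()
            zp[c] += h
            zm[c] -= h
            fd_g = (ocp.objective(zp) - ocp.objective(zm)) / (2 * h)
            assert fd_g == pytest.approx(g[c], rel=1e-4, abs=1e-8)
            fd_h = (ocp.objective_grad(zp) - ocp.objective_grad(zm)) / (2 * h)
            assert np.allclose(fd_h, H[:, c], atol=1e-6)

    def test_defect_jacobian_matches_finite_differences(self, child_model,
                                                        pathological_mtgs, rng):
        cfg = OCPConfig(mode="MAPD", n_shooting=8)
        ocp = assemble_ocp(child_model, pathological_mtgs, None,
                           default_phase_schedule(), cfg)
        z0 = ocp.default_guess()
        eq, Jeq, ineq, Jineq = ocp._evaluate(z0)
        h = 1e-6
        for c in rng.choice(ocp.nvar, 5, replace=False):
            zp, zm = z0.copy(), z0.copy()
            zp[c] += h
            zm[c] -= h
            ocp._cache_key = None
            ep = ocp._evaluate(zp)[0]
            ocp._cache_key = None
            em = ocp._evaluate(zm)[0]
            col = np.asarray(Jeq[:, c].todense()).ravel()
            assert np.allclose((ep - em) / (2 * h), col,
                               atol=1e-5 * max(1, np.abs(col).max()))


class TestPrototype:
    def test_guess_fractions_sum_to_one(self):
        assert GUESS_PHASE_FRACTIONS.sum() == pytest.approx(1.0)

    def test_prototype_contacts_on_ground(self, child_model):
        from torquegait.dynamics import contact_kinematics

        frac = np.linspace(0, 1, 33)
        q, qd = prototype_gait(child_model, 1.1, 0.5, frac)
        ev = np.cumsum(GUESS_PHASE_FRACTIONS)
        for i, sf in enumerate(frac):
            ck = contact_kinematics(child_model, q[i], qd[i])
            # stance-side heel on the ground during foot-flat phases
            if ev[1] < sf < ev[3]:
                assert abs(ck["L_heel"][0][1]) < 0.02
            # swing foot clears the ground mid-swing
            if 0.1 < sf < 0.25:
                assert ck["L_heel"][0][1] > 0.005

    def test_prototype_advances_one_stride(self, child_model):
        frac = np.linspace(0, 1, 17)
        q, _ = prototype_gait(child_model, 1.0, 0.6, frac)
        assert q[-1, 0] - q[0, 0] == pytest.approx(0.6, abs=1e-9)
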