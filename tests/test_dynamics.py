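"""Rigid-body dynamics: oracles for the constrained equations of motion.

The independent references used here are (a) a symbolic Lagrangian
derivation of the same mechanism via sympy, (b) a null-space elimination
solve of the contact-constrained subproblem, (c) conservation laws, and
(d) forward/inverse round trips.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from torquegait.dynamics import (ContactSingularError, DynamicsEngine,
                                 constrained_forward_dynamics,
                                 contact_kinematics,
                                 inverse_dynamics_with_residuals,
                                 linear_momentum, neutral_standing_state,
                                 residual_report, split_stance_state,
                                 total_mechanical_energy)
from torquegait.model import ContactSet, ModelState, build_default_model


def _random_state(rng, model, scale=0.4):
    q = rng.normal(0, scale, 10)
    q[1] += 0.7
    qd = rng.normal(0, 1.0, 10)
    return ModelState(q, qd, np.zeros(14))


class TestFreeDynamics:
    def test_free_fall(self, child_model):
        st = neutral_standing_state(child_model)
        qdd, grf = constrained_forward_dynamics(child_model, st, np.zeros(7),
                                                ContactSet())
        expected = np.zeros(10)
        expected[1] = -child_model.gravity
        assert np.allclose(qdd, expected, atol=1e-10)
        assert grf.total_fz == 0.0

    def test_energy_conserved_in_passive_swing(self, child_model, engine):
        q0 = neutral_standing_state(child_model).q.copy()
        q0[[3, 4, 5, 7]] = [0.2, 0.4, -0.5, -0.3]
        st = ModelState(q0, np.zeros(10), np.zeros(14))

        def rhs(t, y):
            kin = engine.kinematics(y[:10][:, None], y[10:][:, None])
            qdd, _, _ = engine.constrained_qdd(kin, np.zeros((10, 1)),
                                               ContactSet())
            return np.concatenate([y[10:], qdd[:, 0]])

        sol = solve_ivp(rhs, [0, 1.0], np.concatenate([st.q, st.qdot]),
                        rtol=1e-11, atol=1e-13)
        final = ModelState(sol.y[:10, -1], sol.y[10:, -1], np.zeros(14))
        e0 = total_mechanical_energy(child_model, st)
        e1 = total_mechanical_energy(child_model, final)
        assert abs(e1 - e0) / abs(e0) < 1e-8

    def test_momentum_constant_without_gravity_or_contact(self):
        model = build_default_model(24.7, 1.25, gravity=1e-12)
        engine = DynamicsEngine(model)
        tau = np.array([3.0, -2.0, 1.5, -1.0, 2.0, 0.5, -1.5])

        def rhs(t, y):
            kin = engine.kinematics(y[:10][:, None], y[10:][:, None])
            Q = engine.joint_torque_matrix(tau[:, None])
            qdd, _, _ = engine.constrained_qdd(kin, Q, ContactSet())
            return np.concatenate([y[10:], qdd[:, 0]])

        st = _random_state(np.random.default_rng(7), model)
        sol = solve_ivp(rhs, [0, 0.5], np.concatenate([st.q, st.qdot]),
                        rtol=1e-10, atol=1e-12)
        p0 = linear_momentum(model, st)
        p1 = linear_momentum(model, ModelState(sol.y[:10, -1], sol.y[10:, -1],
                                               np.zeros(14)))
        assert np.allclose(p0, p1, atol=1e-7)

    def test_sympy_lagrangian_oracle(self, child_model, rng):
        """Unconstrained accelerations vs an independent symbolic
        Lagrangian derivation of the same 10-DoF mechanism."""
        sympy = pytest.importorskip("sympy")
        import sympy.physics.mechanics as me

        q = me.dynamicsymbols("q0:10")
        t = me.dynamicsymbols._t
        N = me.ReferenceFrame("N")
        segs = child_model.segments
        lengths = {n: s.length for n, s in segs.items()}
        parents = (-1, 0, 0, 2, 3, 0, 5, 6)
        names = ("pelvis", "torso", "thigh_l", "shank_l", "foot_l",
                 "thigh_r", "shank_r", "foot_r")
        joint_local = [None, (0, lengths["pelvis"]), (0, 0),
                       (0, -lengths["thigh_l"]), (0, -lengths["shank_l"]),
                       (0, 0), (0, -lengths["thigh_r"]), (0, -lengths["shank_r"])]
        axis = [(0, 1), (0, 1), (0, -1), (0, -1), (1, 0),
                (0, -1), (0, -1), (1, 0)]

        def ancestors(b):
            out = []
            while b >= 0:
                out.append(b)
                b = parents[b]
            return out

        def rotv(angle, v):
            return ((sympy.cos(angle) * v[0] - sympy.sin(angle) * v[1]) * N.x
                    + (sympy.sin(angle) * v[0] + sympy.cos(angle) * v[1]) * N.z)

        phi = {b: sum(q[a + 2] for a in ancestors(b)) for b in range(8)}
        pos = {0: q[0] * N.x + q[1] * N.z}
        for b in range(1, 8):
            pos[b] = pos[parents[b]] + rotv(phi[parents[b]], joint_local[b])
        KE = PE = 0
        for b, name in enumerate(names):
            s = segs[name]
            com = pos[b] + rotv(phi[b], (axis[b][0] * s.com_offset,
                                         axis[b][1] * s.com_offset))
            vel = com.diff(t, N)
            KE += sympy.Rational(1, 2) * s.mass * (vel.dot(N.x) ** 2
                                                   + vel.dot(N.z) ** 2)
            KE += sympy.Rational(1, 2) * s.inertia_com * sympy.diff(phi[b], t) ** 2
            PE += s.mass * child_model.gravity * com.dot(N.z)
        LM = me.LagrangesMethod(KE - PE, list(q))
        LM.form_lagranges_equations()
        fm = sympy.lambdify((list(q), [qi.diff(t) for qi in q]),
                            [LM.mass_matrix, LM.forcing], modules="numpy",
                            cse=True)

        for _ in range(3):
            st = _random_state(rng, child_model)
            MM, F = fm(st.q, st.qdot)
            qdd_oracle = np.linalg.solve(np.asarray(MM, dtype=float),
                                         np.asarray(F, dtype=float).ravel())
            qdd_pkg, _ = constrained_forward_dynamics(
                child_model, st, np.zeros(7), ContactSet())
            assert np.allclose(qdd_pkg, qdd_oracle, rtol=1e-9, atol=1e-9)


class TestConstrainedDynamics:
    def test_static_split_stance_supports_body_weight(self, child_model, engine):
        st = split_stance_state(child_model)
        contacts = ContactSet(["L_heel", "L_toe", "R_heel", "R_toe"])
        kin = engine.kinematics(st.q[:, None], st.qdot[:, None])
        M, bias = engine.mass_and_bias(kin)
        _, Jc, _ = engine.contact_system(kin, contacts)
        A = np.hstack([engine.joint_torque_matrix(np.eye(7)).reshape(10, 7),
                       np.real(Jc[:, :, 0]).T])
        sol, *_ = np.linalg.lstsq(A, np.real(bias[:, 0]), rcond=None)
        qdd, grf = constrained_forward_dynamics(child_model, st, sol[:7],
                                                contacts)
        assert np.max(np.abs(qdd)) < 1e-9
        assert grf.total_fz == pytest.approx(
            child_model.total_mass * child_model.gravity, rel=1e-12)
        assert grf.total_fx == pytest.approx(0.0, abs=1e-9)

    def test_matches_null_space_elimination_oracle(self, child_model, engine, rng):
        """Constrained accelerations vs an independent Lagrange-multiplier
        solve by null-space elimination of the contact Jacobian."""
        from scipy.linalg import null_space

        contacts = ContactSet(["L_heel", "L_toe"])
        for _ in range(4):
            st = _random_state(rng, child_model, scale=0.3)
            tau = rng.normal(0, 8, 7)
            kin = engine.kinematics(st.q[:, None], st.qdot[:, None])
            M, bias = engine.mass_and_bias(kin)
            _, Jc, crhs = engine.contact_system(kin, contacts)
            Mv = np.real(M[:, :, 0])
            bv = np.real(bias[:, 0])
            J = np.real(Jc[:, :, 0])
            b_c = np.real(crhs[:, 0])
            Q = engine.joint_torque_matrix(tau[:, None])[:, 0]

            qdd_p = np.linalg.pinv(J) @ b_c
            Z = null_space(J)
            y = np.linalg.solve(Z.T @ Mv @ Z, Z.T @ (Q - bv - Mv @ qdd_p))
            qdd_oracle = qdd_p + Z @ y
            lam_oracle = np.linalg.solve(J @ J.T, J @ (Mv @ qdd_oracle + bv - Q))

            qdd, lam, rows = engine.constrained_qdd(kin, Q[:, None], contacts)
            assert np.allclose(qdd[:, 0], qdd_oracle, rtol=1e-8, atol=1e-8)
            assert np.allclose(lam[:, 0], lam_oracle, rtol=1e-8, atol=1e-6)

    def test_contact_point_accelerations_vanish(self, child_model, engine, rng):
        contacts = ContactSet(["R_heel", "R_toe"])
        st = split_stance_state(child_model)
        tau = rng.normal(0, 5, 7)
        kin = engine.kinematics(st.q[:, None], st.qdot[:, None])
        Q = engine.joint_torque_matrix(tau[:, None])
        qdd, _, _ = engine.constrained_qdd(kin, Q, contacts)
        _, Jc, crhs = engine.contact_system(kin, contacts)
        acc = np.real(Jc[:, :, 0]) @ np.real(qdd[:, 0]) - np.real(crhs[:, 0])
        assert np.max(np.abs(acc)) < 1e-9

    def test_degenerate_contact_geometry_raises_named_error(self, child_model):
        # the neutral pose has coincident feet and vertically collinear leg
        # joints: four-point contact is rank deficient there
        st = neutral_standing_state(child_model)
        with pytest.raises(ContactSingularError, match="L_heel"):
            constrained_forward_dynamics(
                child_model, st, np.zeros(7),
                ContactSet(["L_heel", "L_toe", "R_heel", "R_toe"]))

    def test_precondition_violation_rejected(self, child_model):
        st = neutral_standing_state(child_model)
        lifted = ModelState(st.q + np.eye(10)[1] * 0.1, st.qdot, st.act)
        with pytest.raises(ValueError, match="precondition"):
            constrained_forward_dynamics(child_model, lifted, np.zeros(7),
                                         ContactSet(["L_heel"]))


class TestContactKinematics:
    def test_neutral_pose_feet_on_ground(self, child_model):
        st = neutral_standing_state(child_model)
        ck = contact_kinematics(child_model, st.q, st.qdot)
        for point, (pos, vel) in ck.items():
            assert pos[1] == pytest.approx(0.0, abs=1e-12)
            assert np.allclose(vel, 0.0)

    def test_velocity_matches_position_finite_difference(self, child_model, rng):
        st = _random_state(rng, child_model)
        h = 1e-7
        ck = contact_kinematics(child_model, st.q, st.qdot)
        ck_p = contact_kinematics(child_model, st.q + h * st.qdot, st.qdot)
        ck_m = contact_kinematics(child_model, st.q - h * st.qdot, st.qdot)
        for point in ck:
            fd = (ck_p[point][0] - ck_m[point][0]) / (2 * h)
            assert np.allclose(fd, ck[point][1], atol=1e-5)


class TestInverseDynamics:
    def _simulate(self, model, engine, tau, t_end=0.25, n=40):
        st = _random_state(np.random.default_rng(3), model, scale=0.2)

        def rhs(t, y):
            kin = engine.kinematics(y[:10][:, None], y[10:][:, None])
            Q = engine.joint_torque_matrix(tau[:, None])
            qdd, _, _ = engine.constrained_qdd(kin, Q, ContactSet())
            return np.concatenate([y[10:], qdd[:, 0]])

        ts = np.linspace(0, t_end, n)
        sol = solve_ivp(rhs, [0, t_end], np.concatenate([st.q, st.qdot]),
                        t_eval=ts, rtol=1e-11, atol=1e-13)
        q = sol.y[:10].T
        qd = sol.y[10:].T
        qdd = np.array([rhs(0, sol.y[:, i])[10:] for i in range(n)])
        return q, qd, qdd

    def test_round_trip_recovers_applied_torques(self, child_model, engine):
        tau = np.array([2.0, -3.0, 1.0, 0.5, -1.5, 2.5, -0.5])
        q, qd, qdd = self._simulate(child_model, engine, tau)
        tau_rec, residuals = inverse_dynamics_with_residuals(
            child_model, q, qd, qdd)
        assert np.allclose(tau_rec, tau, rtol=1e-6, atol=1e-8)
        assert np.max(np.abs(residuals)) < 1e-7

    def test_vertical_grf_offset_shifts_vertical_residual(self, child_model, engine):
        """Adding +5 N of measured vertical force at every sample lowers the
        mean vertical residual by exactly 5 N (Newton-Euler linearity)."""
        tau = np.zeros(7)
        q, qd, qdd = self._simulate(child_model, engine, tau)
        T = q.shape[0]
        grf0 = {"L": np.zeros((T, 3))}
        grf5 = {"L": np.column_stack([np.zeros(T), np.full(T, 5.0),
                                      np.zeros(T)])}
        _, res0 = inverse_dynamics_with_residuals(child_model, q, qd, qdd, grf0)
        _, res5 = inverse_dynamics_with_residuals(child_model, q, qd, qdd, grf5)
        assert np.mean(res5[:, 1]) - np.mean(res0[:, 1]) == pytest.approx(
            -5.0, abs=1e-9)

    def test_stream_length_mismatch_rejected(self, child_model):
        with pytest.raises(ValueError):
            inverse_dynamics_with_residuals(child_model, np.zeros((5, 10)),
                                            np.zeros((4, 10)),
                                            np.zeros((5, 10)))

    def test_residual_report_shape(self):
        res = np.array([[1.0, 2.0, 0.1], [3.0, -2.0, -0.1]])
        rep = residual_report(res, condition="barefoot")
        block = rep["barefoot"]
        assert block["vertical_N"]["mean"] == pytest.approx(0.0)
        assert block["anterior_posterior_N"]["max"] == 3.0
        assert block["moment_Nm"]["min"] == -0.1


def test_forward_inverse_consistency_on_random_states(child_model, rng):
    """inverse(forward(tau)) == tau at isolated random states."""
    for _ in range(5):
        st = _random_state(rng, child_model)
        tau = rng.normal(0, 10, 7)
        qdd, _ = constrained_forward_dynamics(child_model, st, tau, ContactSet())
        tau_rec, res = inverse_dynamics_with_residuals(
            child_model, st.q[None], st.qdot[None], qdd[None])
        assert np.allclose(tau_rec[0], tau, rtol=1e-6)
        assert np.max(np.abs(res)) < 1e-6
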