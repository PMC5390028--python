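"""Planar floating-base rigid-body dynamics for the 8-segment model.

Everything here is vectorized over a trailing batch axis and written with
analytic (holomorphic) numpy operations only, so that the optimal-control
layer can propagate exact complex-step sensitivities through forward
dynamics and the shooting integrator.

Equations of motion are assembled from per-body point Jacobians:

    M(q) qdd + c(q, qd) - Q_grav = B tau + Jc(q)^T lambda
    Jc(q) qdd + Jc_dot qd = 0          (active contacts)

and the constrained system is solved as one symmetric indefinite KKT
system per evaluation, which yields the generalized accelerations together
with the contact (ground reaction) forces.  A flat foot in full contact is
constrained by the heel position (x and z) plus the toe height; anchoring
both points horizontally would make the constraint Jacobian rank
deficient.
"""

from __future__ import annotations

import numpy as np

from .model import (CONTACT_POINTS, NDOF, NMUSCLES, ContactSet,
                    GroundReaction, ModelState, PlanarModel)
from .mtg import ActivationParams, MTGParams, smoothed_activation_rate

__all__ = [
    "DynamicsEngine", "ContactSingularError", "constrained_forward_dynamics",
    "contact_kinematics", "inverse_dynamics_with_residuals",
    "total_mechanical_energy", "linear_momentum", "neutral_standing_state",
]

_BODIES = ("pelvis", "torso", "thigh_l", "shank_l", "foot_l",
           "thigh_r", "shank_r", "foot_r")
_PARENT = (-1, 0, 0, 2, 3, 0, 5, 6)
# rotation coordinate of body b is q[b + 2]
_NROT = 8

NX = 2 * NDOF + NMUSCLES  # 34 states: q, qdot, activations

#: generalized-coordinate index of each actuated joint, keyed by
#: (joint, side); used to map MTG torques into the dynamics.
JOINT_COORD = {
    ("torso", None): 3,
    ("hip", "L"): 4, ("knee", "L"): 5, ("ankle", "L"): 6,
    ("hip", "R"): 7, ("knee", "R"): 8, ("ankle", "R"): 9,
}

#: sign mapping the generalized ankle coordinate (counter-clockwise
#: positive) to the clinical ankle angle (plantarflexion positive,
#: dorsiflexion negative).
ANKLE_CLINICAL_SIGN = -1.0


class ContactSingularError(RuntimeError):
    """Constrained system is singular for the given contact set."""


def _rot(phi, v):
    """R(phi) @ v for constant v = (vx, vz); phi batched."""
    c, s = np.cos(phi), np.sin(phi)
    return np.stack([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _perp(p):
    """90-degree CCW rotation: S @ p with S = [[0, -1], [1, 0]]."""
    return np.stack([-p[1], p[0]])


class DynamicsEngine:
    """Compiled dynamics for one model (+ optional actuators/orthoses).

    Parameters
    ----------
    model:
        The planar model.
    mtgs:
        Optional list of 14 MTGParams in canonical order; required for
        activation-driven dynamics (`ode_rhs`).
    orthosis_profiles:
        Optional mapping side -> OrthosisProfile adding the ankle
        torque-angle spring law.
    """

    def __init__(self, model: PlanarModel, mtgs: list[MTGParams] | None = None,
                 orthosis_profiles: dict | None = None,
                 activation: ActivationParams = ActivationParams(),
                 act_smooth_width: float = 1e-3):
        self.model = model
        self.mtgs = mtgs
        self.orthosis_profiles = orthosis_profiles or {}
        self.activation = activation
        self.act_smooth_width = act_smooth_width

        segs = [model.segment(n) for n in _BODIES]
        self.masses = np.array([s.mass for s in segs])
        self.inertias = np.array([s.inertia_com for s in segs])
        lengths = {n: s.length for n, s in zip(_BODIES, segs)}

        # joint offset of each body in its parent's (neutral-aligned) frame
        self._joint_local = [
            None,                                   # pelvis: floating base
            np.array([0.0, lengths["pelvis"]]),     # torso at top of pelvis
            np.array([0.0, 0.0]),                   # hips coincide at pelvis origin
            np.array([0.0, -lengths["thigh_l"]]),
            np.array([0.0, -lengths["shank_l"]]),
            np.array([0.0, 0.0]),
            np.array([0.0, -lengths["thigh_r"]]),
            np.array([0.0, -lengths["shank_r"]]),
        ]
        # center-of-mass offset in each body frame (neutral axis direction)
        axis = [np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                np.array([0.0, -1.0]), np.array([0.0, -1.0]), np.array([1.0, 0.0]),
                np.array([0.0, -1.0]), np.array([0.0, -1.0]), np.array([1.0, 0.0])]
        self._com_local = [a * s.com_offset for a, s in zip(axis, segs)]

        # ancestor mask: anc[b, j] true if rotation coordinate j+2 moves body b
        anc = np.zeros((len(_BODIES), _NROT), dtype=bool)
        for b in range(len(_BODIES)):
            node = b
            while node >= 0:
                anc[b, node] = True
                node = _PARENT[node]
        self.anc = anc
        self._rot_inertia = (anc.T * self.inertias) @ anc  # constant rot-rot block
        self._contact_body = {p: (_BODIES.index("foot_l") if p.startswith("L")
                                  else _BODIES.index("foot_r"))
                              for p in CONTACT_POINTS}

        if mtgs is not None:
            self._mtg_sign = np.array([p.sign for p in mtgs])
            self._mtg_tau = np.array([p.tau_max for p in mtgs])
            self._mtg_coord = np.array([JOINT_COORD[(p.joint, p.side)]
                                        for p in mtgs])
            # group actuators sharing identical curve objects so that each
            # distinct curve is evaluated once per call on a stacked input
            def groups(curve_of):
                out = {}
                for i, p in enumerate(mtgs):
                    out.setdefault(id(curve_of(p)), (curve_of(p), []))[1].append(i)
                return [(c, np.array(ix)) for c, ix in out.values()]
            self._fa_groups = groups(lambda p: p.fA)
            self._fv_groups = groups(lambda p: p.fV)

    # ------------------------------------------------------------------
    # kinematics
    # ------------------------------------------------------------------
    def kinematics(self, q, qd):
        """Forward kinematics of all bodies; inputs shaped (10, B)."""
        q = np.atleast_2d(q.T).T if q.ndim == 1 else q
        qd = np.atleast_2d(qd.T).T if qd.ndim == 1 else qd
        B = q.shape[1]
        dtype = np.result_type(q, qd)

        phi = np.einsum("bj,jB->bB", self.anc.astype(float), q[2:])
        phidot = np.einsum("bj,jB->bB", self.anc.astype(float), qd[2:])

        origins = np.empty((len(_BODIES), 2, B), dtype=dtype)
        vels = np.empty_like(origins)
        biases = np.empty_like(origins)
        origins[0] = q[:2]
        vels[0] = qd[:2]
        biases[0] = 0.0
        for b in range(1, len(_BODIES)):
            par = _PARENT[b]
            d = self._joint_local[b]
            rd = _rot(phi[par], d)
            origins[b] = origins[par] + rd
            vels[b] = vels[par] + phidot[par] * _perp(rd)
            biases[b] = biases[par] - phidot[par] ** 2 * rd

        coms = np.empty_like(origins)
        vcoms = np.empty_like(origins)
        bcoms = np.empty_like(origins)
        for b in range(len(_BODIES)):
            rc = _rot(phi[b], self._com_local[b])
            coms[b] = origins[b] + rc
            vcoms[b] = vels[b] + phidot[b] * _perp(rc)
            bcoms[b] = biases[b] - phidot[b] ** 2 * rc

        return dict(q=q, qd=qd, phi=phi, phidot=phidot, origins=origins,
                    vels=vels, biases=biases, coms=coms, vcoms=vcoms,
                    bcoms=bcoms, B=B, dtype=dtype)

    def point_jacobian(self, kin, body: int, p):
        """Jacobian (2, 10, B) of a world point p (2, B) on a body."""
        B = kin["B"]
        J = np.zeros((2, NDOF, B), dtype=np.result_type(kin["dtype"], p.dtype))
        J[0, 0] = 1.0
        J[1, 1] = 1.0
        for j in np.flatnonzero(self.anc[body]):
            J[:, 2 + j] = _perp(p - kin["origins"][j])
        return J

    def _point_state(self, kin, body: int, local):
        """Position, velocity and q̈=0 acceleration of a body-fixed point."""
        rp = _rot(kin["phi"][body], local)
        p = kin["origins"][body] + rp
        v = kin["vels"][body] + kin["phidot"][body] * _perp(rp)
        bias = kin["biases"][body] - kin["phidot"][body] ** 2 * rp
        return p, v, bias

    def contact_point_states(self, kin):
        """Dict point -> (pos, vel, bias, J) for all four contact points."""
        out = {}
        for point in CONTACT_POINTS:
            body = self._contact_body[point]
            local = np.asarray(self.model.contact_points[point])
            p, v, bias = self._point_state(kin, body, local)
            out[point] = (p, v, bias, self.point_jacobian(kin, body, p))
        return out

    # ------------------------------------------------------------------
    # equations of motion
    # ------------------------------------------------------------------
    def mass_and_bias(self, kin):
        """Mass matrix (10, 10, B) and bias force (10, B).

        The bias collects Coriolis/centrifugal terms minus gravity, so that
        M qdd + bias = Q_applied + Jc^T lambda.
        """
        B = kin["B"]
        dtype = kin["dtype"]
        g = self.model.gravity
        masses = self.masses
        # per-(body, rotation) moment arms: S (com_b - axis_j), masked by the
        # kinematic tree; shape (8, 8, 2, B)
        diff = kin["coms"][:, None] - kin["origins"][None, :]
        P = np.empty_like(diff)
        P[:, :, 0] = -diff[:, :, 1]
        P[:, :, 1] = diff[:, :, 0]
        P *= self.anc[:, :, None, None]

        M = np.zeros((NDOF, NDOF, B), dtype=dtype)
        total = masses.sum()
        M[0, 0] = total
        M[1, 1] = total
        T = np.einsum("b,bjiB->jiB", masses, P)            # (8, 2, B)
        M[0, 2:] = T[:, 0]
        M[1, 2:] = T[:, 1]
        M[2:, 0] = T[:, 0]
        M[2:, 1] = T[:, 1]
        M[2:, 2:] = (np.einsum("b,bjiB,bkiB->jkB", masses, P, P)
                     + self._rot_inertia[:, :, None])

        bias = np.empty((NDOF, B), dtype=dtype)
        bc = kin["bcoms"]
        bias[:2] = np.einsum("b,biB->iB", masses, bc)
        bias[2:] = np.einsum("b,bjiB,biB->jB", masses, P, bc)
        # minus gravity generalized force (g acts along -z)
        bias[1] += total * g
        bias[2:] += g * T[:, 1]
        return M, bias

    # ------------------------------------------------------------------
    # contacts
    # ------------------------------------------------------------------
    def contact_rows(self, contacts: ContactSet):
        """Ordered constraint row descriptors (point, component) for a set.

        Per foot in contact: one anterior-posterior anchor row (heel if
        active, else toe) followed by a vertical row per active point.
        """
        rows = []
        for side in contacts.feet:
            pts = contacts.foot_points(side)
            anchor = f"{side}_heel" if f"{side}_heel" in contacts else f"{side}_toe"
            rows.append((anchor, "x"))
            for p in pts:
                rows.append((p, "z"))
        return rows

    def contact_system(self, kin, contacts: ContactSet, baumgarte=(0.0, 0.0)):
        """Constraint Jacobian (nc, 10, B) and acceleration RHS (nc, B)."""
        rows = self.contact_rows(contacts)
        states = self.contact_point_states(kin)
        B = kin["B"]
        nc = len(rows)
        Jc = np.zeros((nc, NDOF, B), dtype=kin["dtype"])
        rhs = np.zeros((nc, B), dtype=kin["dtype"])
        alpha, beta = baumgarte
        for i, (point, comp) in enumerate(rows):
            p, v, bias, J = states[point]
            k = 0 if comp == "x" else 1
            Jc[i] = J[k]
            rhs[i] = -bias[k] - 2.0 * alpha * v[k]
            if comp == "z" and beta:
                rhs[i] -= beta**2 * p[k]
        return rows, Jc, rhs

    def constrained_qdd(self, kin, Q_applied, contacts: ContactSet,
                        baumgarte=(0.0, 0.0), check_singular: bool = False):
        """Solve the contact-constrained equations of motion.

        Returns accelerations (10, B), multipliers (nc, B) and the row
        descriptors.  Multipliers are the physical contact forces (N).
        """
        M, bias = self.mass_and_bias(kin)
        rows, Jc, crhs = self.contact_system(kin, contacts, baumgarte)
        nc = len(rows)
        B = kin["B"]
        n = NDOF + nc
        A = np.zeros((B, n, n), dtype=kin["dtype"])
        A[:, :NDOF, :NDOF] = np.moveaxis(M, -1, 0)
        if nc:
            JcB = np.moveaxis(Jc, -1, 0)
            A[:, :NDOF, NDOF:] = -np.swapaxes(JcB, 1, 2)
            A[:, NDOF:, :NDOF] = JcB
        rhs = np.empty((B, n), dtype=kin["dtype"])
        rhs[:, :NDOF] = (Q_applied - bias).T
        if nc:
            rhs[:, NDOF:] = crhs.T
        if check_singular:
            conds = np.linalg.cond(A)
            if np.any(~np.isfinite(conds)) or np.any(conds > 1e12):
                raise ContactSingularError(
                    f"singular constrained system for contact set "
                    f"{sorted(contacts.active)}")
        try:
            sol = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError as err:
            raise ContactSingularError(
                f"singular constrained system for contact set "
                f"{sorted(contacts.active)}") from err
        qdd = sol[:, :NDOF].T
        lam = sol[:, NDOF:].T
        return qdd, lam, rows

    # ------------------------------------------------------------------
    # actuation
    # ------------------------------------------------------------------
    def generalized_actuation(self, q, qd, act, stiffness=None):
        """Generalized forces (10, B) from MTG activations + orthoses.

        ``stiffness`` optionally overrides the free orthosis spring
        constants as (K_D_L, K_P_L, K_D_R, K_P_R); entries may be complex
        during sensitivity propagation.
        """
        if self.mtgs is None:
            raise ValueError("engine built without MTGs")
        dtype = np.result_type(q, qd, act,
                               *(np.asarray(s) for s in (stiffness,) if s is not None))
        Q = np.zeros((NDOF, q.shape[1]), dtype=dtype)
        sgn, tau, coord = self._mtg_sign, self._mtg_tau, self._mtg_coord
        theta_m = sgn[:, None] * q[coord]
        omega_m = sgn[:, None] * qd[coord]
        fa = np.empty_like(theta_m)
        fv = np.empty_like(omega_m)
        for curve, ix in self._fa_groups:
            fa[ix] = curve(theta_m[ix])
        for curve, ix in self._fv_groups:
            fv[ix] = curve(omega_m[ix])
        contrib = sgn[:, None] * tau[:, None] * act * fa * fv
        np.add.at(Q, coord, contrib)
        for side, profile in self.orthosis_profiles.items():
            ci = JOINT_COORD[("ankle", side)]
            theta_clin = ANKLE_CLINICAL_SIGN * q[ci]
            if stiffness is None:
                kd = kp = None
            else:
                kd, kp = (stiffness[0], stiffness[1]) if side == "L" else (stiffness[2], stiffness[3])
            Q[ci] += ANKLE_CLINICAL_SIGN * profile.torque(theta_clin, K_D=kd, K_P=kp)
        return Q

    def joint_torque_matrix(self, tau_joint):
        """Map 7 joint torques (7, B) to generalized forces (10, B)."""
        Q = np.zeros((NDOF,) + tau_joint.shape[1:], dtype=tau_joint.dtype)
        Q[3:] = tau_joint
        return Q

    # ------------------------------------------------------------------
    # full ODE and shooting integrator
    # ------------------------------------------------------------------
    def ode_rhs(self, x, e, contacts: ContactSet, stiffness=None,
                baumgarte=(0.0, 0.0), return_forces: bool = False):
        """State derivative of x = (q, qdot, a) under excitations e."""
        q, qd, act = x[:NDOF], x[NDOF:2 * NDOF], x[2 * NDOF:]
        kin = self.kinematics(q, qd)
        Q = self.generalized_actuation(q, qd, act, stiffness)
        qdd, lam, rows = self.constrained_qdd(kin, Q, contacts, baumgarte)
        adot = smoothed_activation_rate(e, act, self.activation,
                                        self.act_smooth_width)
        xdot = np.concatenate([qd, qdd, adot], axis=0)
        if return_forces:
            return xdot, lam, rows
        return xdot

    def mech_rhs(self, qqd, a, contacts: ContactSet, stiffness=None,
                 baumgarte=(0.0, 0.0)):
        """Derivative of the mechanical states (q, qdot) at activations a."""
        q, qd = qqd[:NDOF], qqd[NDOF:]
        kin = self.kinematics(q, qd)
        Q = self.generalized_actuation(q, qd, a, stiffness)
        qdd, _, _ = self.constrained_qdd(kin, Q, contacts, baumgarte)
        return np.concatenate([qd, qdd], axis=0)

    def integrate_interval(self, x0, u0, u1, h, contacts: ContactSet,
                           nsub: int, stiffness=None, baumgarte=(0.0, 0.0),
                           act_steps: int = 4):
        """Fixed-step RK4 over one shooting interval of duration h.

        Controls are interpolated linearly between the interval endpoints;
        ``h`` may be batched and complex (duration sensitivities).

        The activation dynamics are much stiffer than the skeleton dynamics
        (activation time constant 11 ms) but are driven one-way: activations
        influence the mechanical states while the converse does not hold.
        The activation subsystem is therefore integrated first on its own
        fine RK4 grid (``act_steps`` steps per half mechanical substep) and
        sampled at the mechanical RK4 stage times, so that the expensive
        contact-constrained solves can run at a coarser step without a
        stability penalty.
        """
        n_half = 2 * nsub
        a = x0[2 * NDOF:]
        a_grid = [a]
        dt_a = h / (n_half * act_steps)
        frac = 1.0 / (n_half * act_steps)
        p, w = self.activation, self.act_smooth_width
        for i in range(n_half):
            for k in range(act_steps):
                s0 = (i * act_steps + k) * frac
                e0 = u0 + (u1 - u0) * s0
                em = u0 + (u1 - u0) * (s0 + 0.5 * frac)
                e1 = u0 + (u1 - u0) * (s0 + frac)
                k1 = smoothed_activation_rate(e0, a, p, w)
                k2 = smoothed_activation_rate(em, a + 0.5 * dt_a * k1, p, w)
                k3 = smoothed_activation_rate(em, a + 0.5 * dt_a * k2, p, w)
                k4 = smoothed_activation_rate(e1, a + dt_a * k3, p, w)
                a = a + (dt_a / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            a_grid.append(a)

        x = x0[:2 * NDOF]
        hs = h / nsub
        for k in range(nsub):
            a0, am, a1 = a_grid[2 * k], a_grid[2 * k + 1], a_grid[2 * k + 2]
            k1 = self.mech_rhs(x, a0, contacts, stiffness, baumgarte)
            k2 = self.mech_rhs(x + 0.5 * hs * k1, am, contacts, stiffness, baumgarte)
            k3 = self.mech_rhs(x + 0.5 * hs * k2, am, contacts, stiffness, baumgarte)
            k4 = self.mech_rhs(x + hs * k3, a1, contacts, stiffness, baumgarte)
            x = x + (hs / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return np.concatenate([x, a_grid[-1]], axis=0)

    def node_forces(self, x, e, contacts: ContactSet, stiffness=None):
        """Contact multipliers and rows at a single (batched) state."""
        q, qd, act = x[:NDOF], x[NDOF:2 * NDOF], x[2 * NDOF:]
        kin = self.kinematics(q, qd)
        Q = self.generalized_actuation(q, qd, act, stiffness)
        _, lam, rows = self.constrained_qdd(kin, Q, contacts)
        return lam, rows


# ----------------------------------------------------------------------
# single-state convenience API
# ----------------------------------------------------------------------

def _as_batch(v):
    return np.asarray(v, dtype=float)[:, None]


def neutral_standing_state(model: PlanarModel) -> ModelState:
    """Upright standing pose with heels and toes exactly at ground height."""
    from .model import standing_height_of_pelvis

    q = np.zeros(NDOF)
    q[1] = standing_height_of_pelvis(model)
    return ModelState(q, np.zeros(NDOF), np.zeros(NMUSCLES))


def split_stance_state(model: PlanarModel, alpha: float = 0.15) -> ModelState:
    """Double-flat stance with straight legs straddled by +/- alpha.

    Both feet are flat on the ground, separated fore-aft.  Unlike the
    neutral pose (feet coincident, leg joints vertically collinear, which
    makes the four-point contact system rank deficient) this pose has a
    full-rank contact Jacobian.
    """
    from .model import standing_height_of_pelvis

    q = np.zeros(NDOF)
    leg = (model.segment("thigh_l").length + model.segment("shank_l").length)
    q[1] = standing_height_of_pelvis(model) - leg * (1.0 - np.cos(alpha))
    q[4], q[6] = alpha, -alpha    # left leg forward, foot kept flat
    q[7], q[9] = -alpha, alpha    # right leg back
    return ModelState(q, np.zeros(NDOF), np.zeros(NMUSCLES))


def contact_kinematics(model: PlanarModel, q, qdot):
    """Positions and velocities of all four contact points.

    Returns dict point -> (position (2,), velocity (2,)).
    """
    eng = DynamicsEngine(model)
    kin = eng.kinematics(_as_batch(q), _as_batch(qdot))
    states = eng.contact_point_states(kin)
    return {p: (np.real(s[0][:, 0]).copy(), np.real(s[1][:, 0]).copy())
            for p, s in states.items()}


def constrained_forward_dynamics(model: PlanarModel, state: ModelState,
                                 tau, contacts: ContactSet,
                                 pos_tol: float = 1e-6, vel_tol: float = 1e-6):
    """Contact-constrained forward dynamics at one state.

    ``tau`` holds the 7 joint torques (torso, hip/knee/ankle left then
    right).  Active contact points must be at ground height with zero
    velocity within ``pos_tol``/``vel_tol``.  Returns the generalized
    accelerations and the ground reaction forces.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (NDOF - 3,):
        raise ValueError("tau must hold the 7 joint torques")
    eng = DynamicsEngine(model)
    kin = eng.kinematics(_as_batch(state.q), _as_batch(state.qdot))
    states = eng.contact_point_states(kin)
    for point in contacts:
        p, v = states[point][0][:, 0], states[point][1][:, 0]
        if abs(p[1]) > pos_tol or np.linalg.norm(v) > vel_tol:
            raise ValueError(
                f"contact point {point} violates the at-ground/zero-velocity "
                f"precondition (z = {p[1]:.2e} m, |v| = {np.linalg.norm(v):.2e} m/s)")
    Q = eng.joint_torque_matrix(tau[:, None])
    qdd, lam, rows = eng.constrained_qdd(kin, Q, contacts, check_singular=True)
    fz = {}
    fx = {}
    for (point, comp), value in zip(rows, lam[:, 0]):
        if comp == "z":
            fz[point] = float(value)
        else:
            fx[point[0]] = float(value)
    return np.real(qdd[:, 0]).copy(), GroundReaction(fz=fz, fx=fx)


def inverse_dynamics_with_residuals(model: PlanarModel, q, qdot, qddot,
                                    grf: dict | None = None):
    """Joint torques and floating-base residuals along a trajectory.

    Parameters
    ----------
    q, qdot, qddot:
        Arrays (T, 10) of coordinates, velocities, accelerations.
    grf:
        Optional mapping side ("L"/"R") -> array (T, 3) of measured
        anterior force (N), vertical force (N) and center-of-pressure X
        position (m).  Measured forces are applied at the center of
        pressure at ground height.

    Returns
    -------
    tau : (T, 7) joint torques; residuals : (T, 3) pelvis-frame
    anterior force, vertical force and sagittal moment left unexplained by
    the measured ground forces.
    """
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qdot, dtype=float)
    qdd = np.asarray(qddot, dtype=float)
    if not (q.shape == qd.shape == qdd.shape) or q.ndim != 2 or q.shape[1] != NDOF:
        raise ValueError("q, qdot, qddot must share shape (T, 10)")
    T = q.shape[0]
    grf = grf or {}
    for side, arr in grf.items():
        if np.asarray(arr).shape != (T, 3):
            raise ValueError(f"grf[{side!r}] must have shape (T, 3)")

    eng = DynamicsEngine(model)
    kin = eng.kinematics(q.T, qd.T)
    M, bias = eng.mass_and_bias(kin)
    Q_req = np.einsum("abB,bB->aB", M, qdd.T) + bias   # (10, T)

    Q_grf = np.zeros((NDOF, T))
    for side, arr in grf.items():
        arr = np.asarray(arr, dtype=float)
        body = _BODIES.index("foot_l" if side == "L" else "foot_r")
        p = np.stack([arr[:, 2], np.zeros(T)])  # force applied at CoP on the ground
        J = eng.point_jacobian(kin, body, p)
        F = np.stack([arr[:, 0], arr[:, 1]])
        Q_grf += np.einsum("iaB,iB->aB", J, F)

    net = Q_req - Q_grf
    residuals = net[:3].T.copy()
    tau = net[3:].T.copy()
    return tau, residuals


def residual_report(residuals: np.ndarray, condition: str = "") -> dict:
    """Mean/min/max summary of floating-base residuals."""
    labels = ("anterior_posterior_N", "vertical_N", "moment_Nm")
    rep = {
        lab: dict(mean=float(np.mean(residuals[:, i])),
                  min=float(np.min(residuals[:, i])),
                  max=float(np.max(residuals[:, i])))
        for i, lab in enumerate(labels)
    }
    if condition:
        rep = {condition: rep}
    return rep


def total_mechanical_energy(model: PlanarModel, state: ModelState) -> float:
    """Kinetic + gravitational potential energy of the full model."""
    eng = DynamicsEngine(model)
    kin = eng.kinematics(_as_batch(state.q), _as_batch(state.qdot))
    ke = 0.0
    pe = 0.0
    for b in range(len(_BODIES)):
        v = kin["vcoms"][b][:, 0]
        ke += 0.5 * eng.masses[b] * float(v @ v)
        ke += 0.5 * eng.inertias[b] * float(kin["phidot"][b][0]) ** 2
        pe += eng.masses[b] * model.gravity * float(kin["coms"][b][1, 0])
    return ke + pe


def linear_momentum(model: PlanarModel, state: ModelState) -> np.ndarray:
    """Total linear momentum (2,) of the model."""
    eng = DynamicsEngine(model)
    kin = eng.kinematics(_as_batch(state.q), _as_batch(state.qdot))
    return sum(eng.masses[b] * np.real(kin["vcoms"][b][:, 0])
               for b in range(len(_BODIES)))
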