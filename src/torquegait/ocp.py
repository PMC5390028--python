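"""Multi-phase gait optimal control.

A full left-right stride is modeled as 8 contact phases (toe-off, heel
strike, foot-flat events in fixed order).  The trajectory optimization is
transcribed by direct multiple shooting: states x = (q, qdot, a) at the
shooting nodes, neural excitations u = e piecewise linear between nodes,
per-phase durations and (optionally) the four orthosis spring stiffnesses
as free parameters.  Interval dynamics are integrated with fixed-step RK4
through the contact-constrained equations of motion; defect, contact,
unilaterality (F_z >= eps), friction-cone and periodicity conditions become
NLP constraints.  Exact constraint Jacobians are obtained by propagating
complex-step sensitivities through the integrator, and the NLP is solved
with scipy's trust-constr interior-point method.

Three objective modes are supported:

* ``LS`` - dynamic least-squares fit to reference joint kinematics at
  fixed phase times, with a small control regularization (weight delta).
* ``MAPD`` - minimal (squared) muscle activation per distance walked, with
  periodicity over the stride.
* ``MAPD_WS`` - MAPD minus lambda * mean walking speed, favoring faster
  gait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, NonlinearConstraint, minimize

from .dynamics import ANKLE_CLINICAL_SIGN, JOINT_COORD, NX, DynamicsEngine
from .model import NDOF, NMUSCLES, ContactSet, PlanarModel
from .mtg import MTGParams

__all__ = [
    "PhaseSpec", "OCPConfig", "Solution", "ReferenceGait",
    "default_phase_schedule", "objective_ls", "objective_mapd",
    "objective_mapd_ws", "assemble_ocp", "solve_ocp",
    "identify_orthosis_stiffness", "prototype_gait",
]

_CS_STEP = 1e-100  # complex-step size; derivatives are exact to roundoff
_NPHASE = 8
#: internal scaling of the stiffness decision variables (Nm/rad per unit)
_K_SCALE = 100.0


# ----------------------------------------------------------------------
# phase schedule
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSpec:
    """One contact phase of the stride."""

    index: int
    name: str
    contacts: ContactSet
    entering: tuple[str, ...]


_SCHEDULE_SETS = (
    ("right_flat__left_toe_off", ("R_heel", "R_toe")),
    ("right_toe_on__right_heel_off", ("R_toe",)),
    ("right_toe_on__left_heel_on", ("R_toe", "L_heel")),
    ("right_toe_on__left_flat", ("R_toe", "L_heel", "L_toe")),
    ("left_flat__right_toe_off", ("L_heel", "L_toe")),
    ("left_toe_on__left_heel_off", ("L_toe",)),
    ("left_toe_on__right_heel_on", ("L_toe", "R_heel")),
    ("left_toe_on__right_flat", ("L_toe", "R_heel", "R_toe")),
)


def default_phase_schedule() -> list[PhaseSpec]:
    """The 8 phases of a left-right stride, starting at left toe off.

    Consecutive phases (periodically closed) differ by exactly one
    heel/toe contact event; newly added contacts are the phase's
    ``entering`` points, position- and velocity-constrained at its start.
    """
    phases = []
    for i, (name, pts) in enumerate(_SCHEDULE_SETS):
        prev = set(_SCHEDULE_SETS[(i - 1) % _NPHASE][1])
        entering = tuple(sorted(set(pts) - prev))
        phases.append(PhaseSpec(index=i + 1, name=name,
                                contacts=ContactSet(pts), entering=entering))
    return phases


# ----------------------------------------------------------------------
# configuration / reference / solution containers
# ----------------------------------------------------------------------

@dataclass
class OCPConfig:
    """Settings of the gait optimal control problem."""

    mode: str = "MAPD"                 # LS | MAPD | MAPD_WS
    transcription: str = "collocation"  # collocation | shooting
    n_shooting: int = 64               # discretization intervals over the stride
    delta: float = 1e-4                # control regularization weight (LS)
    lam: float = 2.0                   # walking-speed weight (MAPD_WS)
    mu_friction: float = 0.8
    fz_min: float = 1.0                # N; "strictly positive" vertical GRF
    W: np.ndarray | None = None        # diagonal tracking weights (LS)
    free_stiffness: bool = False
    stiffness_guess: tuple = (55.0, 5.0, 55.0, 5.0)   # K_D, K_P per L, R
    stiffness_max: float = 400.0
    fixed_durations: np.ndarray | None = None          # s, required for LS
    fix_phase_times: bool = False      # hold durations fixed in MAPD modes
    duration_bounds: tuple = (0.04, 0.20)   # s per phase; stride <= 1.6 s
    stride_time_guess: float = 1.0
    speed_guess: float = 0.5
    r_min: float = 0.20                # m, minimum forward displacement
    grf_constraints: bool = True       # enable unilaterality/friction rows
    enforce_periodicity: bool | None = None   # None: periodic iff MAPD mode
    dt_max: float = 0.05               # s, mechanical integrator substep cap
    act_dt: float = 0.004              # s, activation integrator substep cap
    q_lower: np.ndarray | None = None
    q_upper: np.ndarray | None = None
    qd_limit: float = 12.0
    act_smooth_width: float = 1e-3
    initial_guess: str = "prototype"   # prototype | stance
    guess_jitter: float = 0.01         # rad, deterministic seeded jitter
    seed: int = 0
    restarts: int = 2                  # interior-point warm restarts
    maxiter: int = 1000
    gtol: float = 1e-6
    xtol: float = 1e-10
    feas_tol: float = 2e-6             # acceptance threshold on constraints
    verbose: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("LS", "MAPD", "MAPD_WS"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.transcription not in ("collocation", "shooting"):
            raise ValueError(f"unknown transcription {self.transcription!r}")
        if self.n_shooting % _NPHASE:
            raise ValueError("n_shooting must be a multiple of 8")
        if self.n_shooting < _NPHASE:
            raise ValueError("need at least one interval per phase")
        if self.delta < 0 or self.fz_min < 0 or self.mu_friction <= 0:
            raise ValueError("invalid weights/limits")
        if self.W is None:
            self.W = np.ones(NDOF)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (NDOF,) or np.any(self.W < 0):
            raise ValueError("W must be 10 non-negative diagonal weights")
        if self.fixed_durations is None and (self.mode == "LS"
                                             or self.fix_phase_times):
            raise ValueError("fixed phase durations required")
        if self.fixed_durations is not None:
            self.fixed_durations = np.asarray(self.fixed_durations, dtype=float)
            if self.fixed_durations.shape != (_NPHASE,) or np.any(self.fixed_durations <= 0):
                raise ValueError("fixed_durations must be 8 positive values")
        if self.q_lower is None:
            self.q_lower = np.array([-2.0, 0.30, -0.6, -1.0,
                                     -1.0, -2.2, -1.0, -1.0, -2.2, -1.0])
        if self.q_upper is None:
            self.q_upper = np.array([5.0, 1.20, 0.6, 1.0,
                                     1.3, 0.10, 1.0, 1.3, 0.10, 1.0])


@dataclass(frozen=True)
class ReferenceGait:
    """Measured joint kinematics for the tracking objective.

    ``times`` are the measurement instants (s, strictly increasing) and
    ``q_meas`` the generalized coordinates at those instants.  Phase times
    are fixed from the recording via ``durations``.
    """

    times: np.ndarray
    q_meas: np.ndarray
    durations: np.ndarray
    grf: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.q_meas, dtype=float)
        d = np.asarray(self.durations, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if q.shape != (t.size, NDOF):
            raise ValueError("q_meas must have shape (n_times, 10)")
        if d.shape != (_NPHASE,) or np.any(d <= 0):
            raise ValueError("durations must be 8 positive phase lengths")
        if t[0] < -1e-9 or t[-1] > d.sum() + 1e-9:
            raise ValueError("measurement times outside the stride window")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "q_meas", q)
        object.__setattr__(self, "durations", d)

    @property
    def stride_time(self) -> float:
        return float(self.durations.sum())


@dataclass
class Solution:
    """Result of a gait OCP solve (or a constructed trajectory)."""

    times: np.ndarray            # node times (N+1,)
    states: np.ndarray           # (N+1, 34): q, qdot, a
    controls: np.ndarray         # (N+1, 14): e
    durations: np.ndarray        # (8,)
    objective: float = math.nan
    mode: str = ""
    stiffness: np.ndarray | None = None   # (K_D_L, K_P_L, K_D_R, K_P_R)
    status: str = ""
    success: bool = False
    constr_violation: float = math.nan
    grf_nodes: list = field(default_factory=list)   # (rows, lam) per node
    node_phase: np.ndarray | None = None

    @property
    def T(self) -> float:
        return float(self.durations.sum())

    @property
    def r_T(self) -> float:
        """Forward pelvis displacement over the stride (m)."""
        return float(self.states[-1, 0] - self.states[0, 0])

    @property
    def walking_speed(self) -> float:
        return self.r_T / self.T

    def q(self) -> np.ndarray:
        return self.states[:, :NDOF]

    def qdot(self) -> np.ndarray:
        return self.states[:, NDOF:2 * NDOF]

    def act(self) -> np.ndarray:
        return self.states[:, 2 * NDOF:]

    def phase_start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)])

    def interp_states(self, t) -> np.ndarray:
        """Piecewise-linear interpolation of the node states at times t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("time outside trajectory support")
        out = np.empty((t.size, self.states.shape[1]))
        for c in range(self.states.shape[1]):
            out[:, c] = np.interp(t, self.times, self.states[:, c])
        return out


# ----------------------------------------------------------------------
# objectives (shared by the transcription and standalone evaluation)
# ----------------------------------------------------------------------

def _pl_square_integral(values: np.ndarray, times: np.ndarray) -> float:
    """Integral of sum-of-squares of piecewise-linear signals.

    ``values`` shaped (n_nodes, n_channels); exact for linear
    interpolation: per interval h/3 (v0^2 + v0 v1 + v1^2) per channel.
    """
    h = np.diff(times)
    v0 = values[:-1]
    v1 = values[1:]
    per = (h[:, None] / 3.0) * (v0**2 + v0 * v1 + v1**2)
    return float(per.sum())


def objective_ls(traj: Solution, ref: ReferenceGait,
                 W: np.ndarray | None = None, delta: float = 1e-4) -> float:
    """Tracking objective: weighted squared kinematic error at the
    measurement times plus ``delta`` times the integrated squared controls."""
    W = np.ones(NDOF) if W is None else np.asarray(W, dtype=float)
    qs = traj.interp_states(ref.times)[:, :NDOF]
    err = qs - ref.q_meas
    track = float(np.sum(err**2 * W))
    reg = delta * _pl_square_integral(traj.controls, traj.times)
    return track + reg


def objective_mapd(traj: Solution) -> float:
    """Squared muscle activations integrated over the stride, per distance."""
    r = traj.r_T
    if r <= 0:
        raise ValueError("model did not move forward (r(T) <= 0)")
    return _pl_square_integral(traj.act(), traj.times) / r


def objective_mapd_ws(traj: Solution, lam: float = 2.0) -> float:
    """MAPD objective minus ``lam`` times the mean walking speed."""
    return objective_mapd(traj) - lam * traj.r_T / traj.T


# ----------------------------------------------------------------------
# initial guesses
# ----------------------------------------------------------------------

#: initial phase-duration fractions of the stride: long foot-flat single
#: support, shorter toe-only push-off, brief heel-strike transition, then
#: double support (left then right half-stride, symmetric).
GUESS_PHASE_FRACTIONS = np.array([0.19, 0.12, 0.04, 0.15] * 2)


def prototype_gait(model: PlanarModel, stride_time: float, speed: float,
                   node_fractions, seed: int = 0, jitter: float = 0.0,
                   swing_lift: float = 0.04, pitch_max: float = 0.25,
                   ankle_range: float = 1.0):
    """Kinematic walking prototype used to seed the optimization.

    Foot placements are planned from the stride length (stance heel
    stationary on the ground, cosine swing profile with ground clearance)
    and the leg joint angles follow from closed-form two-link inverse
    kinematics with flat feet, so the guess respects the contact geometry
    of the phase schedule.  It is not dynamically consistent; it only
    places the iterate in the basin of a walking solution.

    ``node_fractions`` are the stride fractions (0..1) of the shooting
    nodes.  Returns (q, qdot) arrays.
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(node_fractions, dtype=float)
    n_nodes = s.size
    stride = speed * stride_time
    l_th = model.segment("thigh_l").length
    l_sh = model.segment("shank_l").length
    leg_len = l_th + l_sh
    heel_local = np.asarray(model.contact_points["L_heel"])
    ankle_h = -heel_local[1]
    ankle_from_heel = -heel_local[0]

    ev = np.cumsum(GUESS_PHASE_FRACTIONS)   # phase end fractions
    lhs = ev[1]                             # left heel strike (phase 3 start)
    rtoff, rhs_frac = ev[3], ev[5]          # right toe off / heel strike
    lead = 0.22 * stride                    # heel lead over pelvis at landing
    toe_dist = (model.contact_points["L_toe"][0]
                - model.contact_points["L_heel"][0])
    z_liftoff = np.sin(pitch_max) * toe_dist

    def heel_x(side, sf):
        """Planned heel position; stationary in stance, smooth swing with
        zero touchdown velocity."""
        if side == "L":
            t0, t1 = 0.0, lhs               # swing window within [0, 1]
            x_land = stride * lhs + lead
        else:
            t0, t1 = rtoff, rhs_frac
            x_land = stride * rhs_frac + lead
        x_prev = x_land - stride
        if sf < t0:
            return x_prev, 0.0
        if sf >= t1:
            return x_land, 0.0
        u = (sf - t0) / (t1 - t0)
        x = x_prev + stride * 0.5 * (1 - np.cos(np.pi * u))
        z = z_liftoff * (1 - u) ** 2 + swing_lift * np.sin(np.pi * u) ** 2
        return x, z

    def foot_pitch(side, sf):
        """Heel-off pitch (about the toe) during the toe-only window."""
        if side == "R" and ev[0] <= sf < rtoff:
            return -pitch_max * (sf - ev[0]) / (rtoff - ev[0])
        if side == "L" and sf >= ev[4]:
            return -pitch_max * (sf - ev[4]) / (1.0 - ev[4])
        return 0.0

    def leg_ik(hip_pt, ankle_pt):
        d = ankle_pt - hip_pt
        r = float(np.hypot(d[0], d[1]))
        r = min(r, 0.98 * leg_len)
        cos_int = np.clip((l_th**2 + l_sh**2 - r**2) / (2 * l_th * l_sh), -1, 1)
        interior = np.arccos(cos_int)
        gamma = np.arctan2(d[0], -d[1])     # from straight down, + forward
        beta = np.arccos(np.clip((l_th**2 + r**2 - l_sh**2) / (2 * l_th * r), -1, 1))
        return gamma + beta, -(np.pi - interior)

    q = np.zeros((n_nodes, NDOF))
    pz = ankle_h + np.sqrt(max(leg_len**2 - (0.50 * stride) ** 2,
                               (0.55 * leg_len) ** 2)) - 0.01
    for i, sf in enumerate(s):
        px = stride * sf
        hip_pt = np.array([px, pz])
        q[i, 0], q[i, 1] = px, pz
        q[i, 2] = 0.03
        q[i, 3] = 0.03
        for side, cols in (("L", (4, 5, 6)), ("R", (7, 8, 9))):
            psi = foot_pitch(side, sf)
            hx, hz = heel_x(side, sf)
            if psi:
                # ankle from the toe anchor with the foot pitched heel-up
                toe = np.array([hx + toe_dist, 0.0])
                rot = np.array([[np.cos(psi), -np.sin(psi)],
                                [np.sin(psi), np.cos(psi)]])
                heel_pitched = toe + rot @ np.array([-toe_dist, 0.0])
                ankle_pt = heel_pitched + rot @ np.array([ankle_from_heel, ankle_h])
            else:
                ankle_pt = np.array([hx + ankle_from_heel, hz + ankle_h])
            q_hip, q_knee = leg_ik(hip_pt, ankle_pt)
            q[i, cols[0]], q[i, cols[1]] = q_hip, q_knee
            q[i, cols[2]] = np.clip(psi - (q[i, 2] + q_hip + q_knee),
                                    -ankle_range, ankle_range)
    if jitter:
        q[:, 2:] += rng.normal(0.0, jitter, size=(n_nodes, NDOF - 2))
    times = s * stride_time
    qd = np.gradient(q, times, axis=0) if n_nodes > 2 else np.zeros_like(q)
    return q, qd


def _stance_guess(model: PlanarModel, n_nodes: int, seed: int, jitter: float):
    from .dynamics import split_stance_state

    rng = np.random.default_rng(seed)
    st = split_stance_state(model)
    q = np.tile(st.q, (n_nodes, 1))
    q[:, 2:] += rng.normal(0.0, max(jitter, 1e-3), size=(n_nodes, NDOF - 2))
    return q, np.zeros_like(q)


# ----------------------------------------------------------------------
# transcription
# ----------------------------------------------------------------------

class GaitOCP:
    """Direct multiple-shooting transcription of the gait problem."""

    def __init__(self, model: PlanarModel, mtgs: list[MTGParams],
                 schedule: list[PhaseSpec], config: OCPConfig,
                 orthosis_profiles: dict | None = None,
                 reference: ReferenceGait | None = None):
        if len(schedule) != _NPHASE:
            raise ValueError("schedule must have 8 phases")
        if len(mtgs) != NMUSCLES:
            raise ValueError("need 14 MTGs")
        if config.mode == "LS" and reference is None:
            raise ValueError("LS mode requires a ReferenceGait")
        self.model = model
        self.config = config
        self.schedule = schedule
        self.reference = reference
        self.free_durations = config.mode != "LS" and not config.fix_phase_times
        self.free_stiffness = bool(config.free_stiffness)
        if self.free_stiffness and not orthosis_profiles:
            raise ValueError("free stiffness requires orthosis profiles")
        self.engine = DynamicsEngine(
            model, mtgs, orthosis_profiles,
            act_smooth_width=config.act_smooth_width)

        self.N = config.n_shooting
        self.npp = self.N // _NPHASE
        self.node_phase = np.minimum(np.arange(self.N + 1) // self.npp,
                                     _NPHASE - 1)
        if self.free_durations:
            self.durations = None  # decision variables
        else:
            self.durations = config.fixed_durations.copy()

        # substeps per interval, capped by dt_max at the duration upper bound
        if self.free_durations:
            h_ub = config.duration_bounds[1] / self.npp
        else:
            h_ub = float(np.max(self.durations)) / self.npp
        self.nsub = max(2, math.ceil(h_ub / config.dt_max))
        self.act_steps = max(1, math.ceil(h_ub / (2 * self.nsub * config.act_dt)))

        # variable layout
        self.nx_block = (self.N + 1) * NX
        self.nu_block = (self.N + 1) * NMUSCLES
        self.nd = _NPHASE if self.free_durations else 0
        self.npar = 4 if self.free_stiffness else 0
        self.nvar = self.nx_block + self.nu_block + self.nd + self.npar
        self._cache_key = None
        self._cache_val = None
        # ground-reaction rows are expressed in units of body weight so
        # that all constraint families share a comparable scale
        self.force_scale = 1.0 / (model.total_mass * model.gravity)
        self._build_structure()

    # -- variable packing ---------------------------------------------
    def x_idx(self, k):
        return slice(k * NX, (k + 1) * NX)

    def u_idx(self, k):
        return slice(self.nx_block + k * NMUSCLES,
                     self.nx_block + (k + 1) * NMUSCLES)

    @property
    def d_idx(self):
        return slice(self.nx_block + self.nu_block,
                     self.nx_block + self.nu_block + self.nd)

    @property
    def p_idx(self):
        off = self.nx_block + self.nu_block + self.nd
        return slice(off, off + self.npar)

    def unpack(self, z):
        X = z[:self.nx_block].reshape(self.N + 1, NX)
        U = z[self.nx_block:self.nx_block + self.nu_block].reshape(self.N + 1, NMUSCLES)
        D = z[self.d_idx] if self.nd else self.durations
        P = z[self.p_idx] * _K_SCALE if self.npar else None
        return X, U, D, P

    def pack(self, X, U, D=None, P=None):
        parts = [np.asarray(X).ravel(), np.asarray(U).ravel()]
        if self.nd:
            parts.append(np.asarray(D, dtype=float))
        if self.npar:
            parts.append(np.asarray(P, dtype=float) / _K_SCALE)
        return np.concatenate(parts)

    # -- constraint structure ------------------------------------------
    def _build_structure(self):
        cfg = self.config
        self.eq_rows = self.N * NX          # defects
        self.entry_rows = []                # (node, point, kind) kind in pos_z, vel_x, vel_z
        for j, phase in enumerate(self.schedule):
            k = j * self.npp
            cset = phase.contacts
            for point in phase.entering:
                side = point[0]
                anchor = (f"{side}_heel" in cset and point.endswith("heel")) or \
                         (f"{side}_heel" not in cset)
                self.entry_rows.append((k, point, "pos_z"))
                self.entry_rows.append((k, point, "vel_z"))
                if anchor:
                    self.entry_rows.append((k, point, "vel_x"))
        # anchoring of the initial contact set at node 0
        for point in self.schedule[0].contacts:
            side = point[0]
            anchor = point.endswith("heel") or f"{side}_heel" not in self.schedule[0].contacts
            self.entry_rows.append((0, point, "pos_z"))
            self.entry_rows.append((0, point, "vel_z"))
            if anchor:
                self.entry_rows.append((0, point, "vel_x"))
        self.eq_rows += len(self.entry_rows)
        self.periodic = (cfg.mode in ("MAPD", "MAPD_WS")
                         if cfg.enforce_periodicity is None
                         else bool(cfg.enforce_periodicity))
        if self.periodic:
            self.eq_rows += (NX - 1) + NMUSCLES   # states except pelvis x; controls

        # inequality structure per node
        self.node_ineq = []   # (node, phase_idx) with counts derived on the fly
        for k in range(self.N + 1):
            self.node_ineq.append((k, int(self.node_phase[min(k, self.N - 1)])))

    # -- bounds --------------------------------------------------------
    def variable_bounds(self):
        cfg = self.config
        lb = np.empty(self.nvar)
        ub = np.empty(self.nvar)
        x_lb = np.concatenate([cfg.q_lower, -cfg.qd_limit * np.ones(NDOF),
                               np.zeros(NMUSCLES)])
        x_ub = np.concatenate([cfg.q_upper, cfg.qd_limit * np.ones(NDOF),
                               np.ones(NMUSCLES)])
        for k in range(self.N + 1):
            lb[self.x_idx(k)] = x_lb
            ub[self.x_idx(k)] = x_ub
        lb[self.nx_block:self.nx_block + self.nu_block] = 0.0
        ub[self.nx_block:self.nx_block + self.nu_block] = 1.0
        if self.nd:
            lb[self.d_idx] = cfg.duration_bounds[0]
            ub[self.d_idx] = cfg.duration_bounds[1]
        if self.npar:
            lb[self.p_idx] = 0.0
            ub[self.p_idx] = cfg.stiffness_max / _K_SCALE
        if self.periodic:
            # pin the stride origin
            lb[0] = ub[0] = 0.0
        return Bounds(lb, ub)

    # -- dynamics propagation with sensitivities -----------------------
    def _propagate(self, x0, u0, u1, h, phase: PhaseSpec, P):
        """Endpoint of one interval plus Jacobians via complex step.

        Returns (xf, Jx (34,34), Ju0, Ju1, Jh (34,), Jp (34,npar)).
        """
        ncol = 1 + NX + 2 * NMUSCLES + 1 + self.npar
        xb = np.tile(x0[:, None], (1, ncol)).astype(complex)
        ub0 = np.tile(u0[:, None], (1, ncol)).astype(complex)
        ub1 = np.tile(u1[:, None], (1, ncol)).astype(complex)
        hb = np.full(ncol, h, dtype=complex)
        c = 1
        for i in range(NX):
            xb[i, c] += 1j * _CS_STEP
            c += 1
        for i in range(NMUSCLES):
            ub0[i, c] += 1j * _CS_STEP
            c += 1
        for i in range(NMUSCLES):
            ub1[i, c] += 1j * _CS_STEP
            c += 1
        hb[c] += 1j * _CS_STEP
        c += 1
        stiff = None
        if self.npar:
            stiff = np.tile(np.asarray(P, dtype=float)[:, None], (1, ncol)).astype(complex)
            for i in range(4):
                stiff[i, c] += 1j * _CS_STEP * _K_SCALE
                c += 1
        xf = self.engine.integrate_interval(xb, ub0, ub1, hb, phase.contacts,
                                            self.nsub, stiffness=stiff,
                                            act_steps=self.act_steps)
        val = np.real(xf[:, 0]).copy()
        sens = np.imag(xf[:, 1:]) / _CS_STEP
        Jx = sens[:, :NX]
        Ju0 = sens[:, NX:NX + NMUSCLES]
        Ju1 = sens[:, NX + NMUSCLES:NX + 2 * NMUSCLES]
        Jh = sens[:, NX + 2 * NMUSCLES]
        Jp = sens[:, NX + 2 * NMUSCLES + 1:] if self.npar else None
        return val, Jx, Ju0, Ju1, Jh, Jp

    def _node_dynamics(self, x, u, P, phase: PhaseSpec):
        """State derivative f(x, u) and its Jacobians at one node.

        Complex-step over the node state, node control and (if free) the
        stiffness parameters; used by the collocation defects.
        """
        ncol = 1 + NX + NMUSCLES + self.npar
        xb = np.tile(x[:, None], (1, ncol)).astype(complex)
        ub = np.tile(u[:, None], (1, ncol)).astype(complex)
        for i in range(NX):
            xb[i, 1 + i] += 1j * _CS_STEP
        for i in range(NMUSCLES):
            ub[i, 1 + NX + i] += 1j * _CS_STEP
        stiff = None
        if self.npar:
            stiff = np.tile(np.asarray(P, dtype=float)[:, None],
                            (1, ncol)).astype(complex)
            for i in range(4):
                stiff[i, 1 + NX + NMUSCLES + i] += 1j * _CS_STEP * _K_SCALE
        xdot = self.engine.ode_rhs(xb, ub, phase.contacts, stiffness=stiff)
        f = np.real(xdot[:, 0]).copy()
        sens = np.imag(xdot[:, 1:]) / _CS_STEP
        Jx = sens[:, :NX]
        Ju = sens[:, NX:NX + NMUSCLES]
        Jp = sens[:, NX + NMUSCLES:] if self.npar else None
        return f, Jx, Ju, Jp

    def _node_quantities(self, x, P, phase: PhaseSpec, next_contacts=None):
        """Contact forces, point heights/velocities + Jacobians at a node.

        Complex-step over the node state (and stiffness parameters).
        """
        ncol = 1 + NX + self.npar
        xb = np.tile(x[:, None], (1, ncol)).astype(complex)
        for i in range(NX):
            xb[i, 1 + i] += 1j * _CS_STEP
        stiff = None
        if self.npar:
            stiff = np.tile(np.asarray(P, dtype=float)[:, None], (1, ncol)).astype(complex)
            for i in range(4):
                stiff[i, 1 + NX + i] += 1j * _CS_STEP * _K_SCALE
        q, qd, act = xb[:NDOF], xb[NDOF:2 * NDOF], xb[2 * NDOF:]
        kin = self.engine.kinematics(q, qd)
        lam = rows = None
        if len(phase.contacts):
            Q = self.engine.generalized_actuation(q, qd, act, stiff)
            _, lam, rows = self.engine.constrained_qdd(kin, Q, phase.contacts)
        pstates = self.engine.contact_point_states(kin)
        return lam, rows, pstates

    # -- constraint evaluation -----------------------------------------
    def _evaluate(self, z):
        key = z.tobytes()
        if self._cache_key == key:
            return self._cache_val
        X, U, D, P = self.unpack(z)
        cfg = self.config
        h_phase = np.asarray(D, dtype=float) / self.npp

        eq = np.empty(self.eq_rows)
        Jeq = sp.lil_matrix((self.eq_rows, self.nvar))
        row = 0
        eye = np.eye(NX)
        if self.config.transcription == "collocation":
            # trapezoidal defects; node dynamics cached per (node, phase)
            nd_cache = {}

            def node_dyn(k, j):
                key = (k, j)
                if key not in nd_cache:
                    nd_cache[key] = self._node_dynamics(X[k], U[k], P,
                                                        self.schedule[j])
                return nd_cache[key]

            for k in range(self.N):
                j = int(self.node_phase[k])
                f0, Jx0, Ju0, Jp0 = node_dyn(k, j)
                f1, Jx1, Ju1, Jp1 = node_dyn(k + 1, j)
                hk = h_phase[j]
                r = slice(row, row + NX)
                eq[r] = X[k + 1] - X[k] - 0.5 * hk * (f0 + f1)
                Jeq[r, self.x_idx(k)] = -eye - 0.5 * hk * Jx0
                Jeq[r, self.x_idx(k + 1)] = eye - 0.5 * hk * Jx1
                Jeq[r, self.u_idx(k)] = -0.5 * hk * Ju0
                Jeq[r, self.u_idx(k + 1)] = -0.5 * hk * Ju1
                if self.nd:
                    col = self.nx_block + self.nu_block + j
                    Jeq[r, col] = -((f0 + f1) / (2.0 * self.npp))[:, None]
                if self.npar:
                    # sensitivities are already w.r.t. the scaled variables
                    Jeq[r, self.p_idx] = -0.5 * hk * (Jp0 + Jp1)
                row += NX
        else:
            # multiple shooting defects
            for k in range(self.N):
                j = int(self.node_phase[k])
                phase = self.schedule[j]
                val, Jx, Ju0, Ju1, Jh, Jp = self._propagate(
                    X[k], U[k], U[k + 1], h_phase[j], phase, P)
                r = slice(row, row + NX)
                eq[r] = X[k + 1] - val
                Jeq[r, self.x_idx(k + 1)] = eye
                Jeq[r, self.x_idx(k)] = -Jx
                Jeq[r, self.u_idx(k)] = -Ju0
                Jeq[r, self.u_idx(k + 1)] = -Ju1
                if self.nd:
                    col = self.nx_block + self.nu_block + j
                    Jeq[r, col] = -Jh[:, None] / self.npp
                if self.npar:
                    Jeq[r, self.p_idx] = -Jp
                row += NX

        # contact entry / initial anchoring rows and node inequalities
        n_ineq, ineq, Jineq = self._node_constraints(X, U, P, eq, Jeq, row)
        row += len(self.entry_rows)

        if self.periodic:
            # states periodic except pelvis x; controls periodic
            keep = np.arange(1, NX)
            r = slice(row, row + keep.size)
            eq[r] = X[self.N, keep] - X[0, keep]
            JN = sp.lil_matrix((keep.size, NX))
            J0 = sp.lil_matrix((keep.size, NX))
            for i, c in enumerate(keep):
                JN[i, c] = 1.0
                J0[i, c] = -1.0
            Jeq[r, self.x_idx(self.N)] = JN
            Jeq[r, self.x_idx(0)] = J0
            row += keep.size
            r = slice(row, row + NMUSCLES)
            eq[r] = U[self.N] - U[0]
            Jeq[r, self.u_idx(self.N)] = np.eye(NMUSCLES)
            Jeq[r, self.u_idx(0)] = -np.eye(NMUSCLES)
            row += NMUSCLES
        assert row == self.eq_rows

        result = (eq, Jeq.tocsr(), ineq, Jineq.tocsr())
        self._cache_key = key
        self._cache_val = result
        return result

    def _node_constraints(self, X, U, P, eq, Jeq, eq_row0):
        """Entry equality rows + all node inequality rows (GRF, clearance,
        forward progress)."""
        cfg = self.config
        entry_by_node = {}
        for (k, point, kind) in self.entry_rows:
            entry_by_node.setdefault(k, []).append((point, kind))

        ineq_vals = []
        ineq_rows = []   # (cols, jac_row) lists for sparse assembly
        eq_row = eq_row0

        for k in range(self.N + 1):
            j = int(self.node_phase[min(k, self.N - 1)])
            phase = self.schedule[j]
            lam, rows, pstates = self._node_quantities(X[k], P, phase)

            # entering-contact equalities at this node
            for (point, kind) in entry_by_node.get(k, []):
                p, v, _, _ = pstates[point]
                if kind == "pos_z":
                    series = p[1]
                elif kind == "vel_z":
                    series = v[1]
                else:
                    series = v[0]
                eq[eq_row] = np.real(series[0])
                sens = np.imag(series[1:1 + NX]) / _CS_STEP
                Jeq[eq_row, self.x_idx(k)] = sens
                if self.npar:
                    psens = np.imag(series[1 + NX:]) / (_CS_STEP * _K_SCALE) * _K_SCALE
                    Jeq[eq_row, self.p_idx] = psens
                eq_row += 1

            # ground-reaction inequalities (body-weight units)
            if lam is not None and cfg.grf_constraints:
                fs = self.force_scale
                lam_val = np.real(lam[:, 0])
                lam_sens_x = np.imag(lam[:, 1:1 + NX]) / _CS_STEP
                lam_sens_p = (np.imag(lam[:, 1 + NX:]) / _CS_STEP
                              if self.npar else None)
                by_side = {}
                for i, (point, comp) in enumerate(rows):
                    by_side.setdefault(point[0], []).append((i, point, comp))
                for side, items in by_side.items():
                    z_ids = [i for i, _, comp in items if comp == "z"]
                    x_ids = [i for i, _, comp in items if comp == "x"]
                    for i in z_ids:
                        ineq_vals.append((lam_val[i] - cfg.fz_min) * fs)
                        ineq_rows.append((k, lam_sens_x[i] * fs,
                                          lam_sens_p[i] * fs if self.npar else None))
                    if x_ids:
                        fx_i = x_ids[0]
                        fz_sum = sum(lam_val[i] for i in z_ids)
                        fz_sens = sum(lam_sens_x[i] for i in z_ids)
                        fz_sens_p = (sum(lam_sens_p[i] for i in z_ids)
                                     if self.npar else None)
                        mu = cfg.mu_friction
                        for sgn in (+1.0, -1.0):
                            ineq_vals.append((mu * fz_sum + sgn * lam_val[fx_i]) * fs)
                            sx = (mu * fz_sens + sgn * lam_sens_x[fx_i]) * fs
                            spn = ((mu * fz_sens_p + sgn * lam_sens_p[fx_i]) * fs
                                   if self.npar else None)
                            ineq_rows.append((k, sx, spn))

            # swing clearance for inactive points
            for point, (p, v, _, _) in pstates.items():
                if point in phase.contacts:
                    continue
                ineq_vals.append(np.real(p[1][0]))
                sens = np.imag(p[1][1:1 + NX]) / _CS_STEP
                psens = (np.imag(p[1][1 + NX:]) / _CS_STEP if self.npar else None)
                ineq_rows.append((k, sens, psens))

        n_ineq = len(ineq_vals) + (1 if self.periodic else 0)
        ineq = np.empty(n_ineq)
        Jineq = sp.lil_matrix((n_ineq, self.nvar))
        for i, (val, (k, sx, spn)) in enumerate(zip(ineq_vals, ineq_rows)):
            ineq[i] = val
            Jineq[i, self.x_idx(k)] = sx
            if self.npar and spn is not None:
                Jineq[i, self.p_idx] = spn
        if self.periodic:
            # forward progress: px(T) - px(0) >= r_min
            i = n_ineq - 1
            ineq[i] = X[self.N, 0] - X[0, 0] - cfg.r_min
            Jineq[i, self.x_idx(self.N).start] = 1.0
            Jineq[i, self.x_idx(0).start] = -1.0
        return n_ineq, ineq, Jineq

    def constraint_breakdown(self, z) -> dict:
        """Worst violation per constraint family (diagnostic)."""
        eq, _, ineq, _ = self._evaluate(z)
        out = {}
        row = 0
        dq = dqd = da = 0.0
        for k in range(self.N):
            v = eq[row:row + NX]
            row += NX
            dq = max(dq, float(np.max(np.abs(v[:NDOF]))))
            dqd = max(dqd, float(np.max(np.abs(v[NDOF:2 * NDOF]))))
            da = max(da, float(np.max(np.abs(v[2 * NDOF:]))))
        out.update(defect_q=dq, defect_qd=dqd, defect_act=da)
        for (k, point, kind), val in zip(self.entry_rows,
                                         eq[row:row + len(self.entry_rows)]):
            key = f"entry_{kind}"
            out[key] = max(out.get(key, 0.0), float(abs(val)))
        row += len(self.entry_rows)
        if self.periodic:
            out["periodicity"] = float(np.max(np.abs(eq[row:])))
        out["ineq_worst"] = float(-min(0.0, np.min(ineq))) if ineq.size else 0.0
        return out

    # -- objective ------------------------------------------------------
    def node_times(self, D) -> np.ndarray:
        h = np.repeat(np.asarray(D, dtype=float) / self.npp, self.npp)
        return np.concatenate([[0.0], np.cumsum(h)])

    def objective(self, z):
        val, _ = self._objective_and_grad(z)
        return val

    def objective_grad(self, z):
        _, grad = self._objective_and_grad(z)
        return grad

    def _objective_and_grad(self, z):
        X, U, D, P = self.unpack(z)
        cfg = self.config
        grad = np.zeros(self.nvar)
        times = self.node_times(D)
        h = np.diff(times)

        if cfg.mode == "LS":
            ref = self.reference
            idx = np.clip(np.searchsorted(times, ref.times, side="right") - 1,
                          0, self.N - 1)
            w = (ref.times - times[idx]) / h[idx]
            track = 0.0
            for m in range(ref.times.size):
                k = idx[m]
                qm = (1 - w[m]) * X[k, :NDOF] + w[m] * X[k + 1, :NDOF]
                err = qm - ref.q_meas[m]
                track += float(err @ (cfg.W * err))
                gq = 2.0 * cfg.W * err
                grad[k * NX:k * NX + NDOF] += (1 - w[m]) * gq
                grad[(k + 1) * NX:(k + 1) * NX + NDOF] += w[m] * gq
            reg, dreg_u = self._quad_cost(U, h)
            val = track + cfg.delta * reg
            for k in range(self.N + 1):
                grad[self.u_idx(k)] += cfg.delta * dreg_u[k]
            return val, grad

        A = X[:, 2 * NDOF:]
        Ja, dJa_dA = self._quad_cost(A, h)
        # derivative of the quadrature w.r.t. interval lengths
        v0, v1 = A[:-1], A[1:]
        per_interval = np.sum((v0**2 + v0 * v1 + v1**2) / 3.0, axis=1)
        dJa_dD = np.array([per_interval[self.node_phase[:self.N] == j].sum()
                           for j in range(_NPHASE)]) / self.npp
        r = X[self.N, 0] - X[0, 0]
        T = float(np.sum(D))
        val = Ja / r
        for k in range(self.N + 1):
            grad[k * NX + 2 * NDOF:(k + 1) * NX] += dJa_dA[k] / r
        grad[self.N * NX] += -Ja / r**2
        grad[0] += Ja / r**2
        if self.nd:
            grad[self.d_idx] += dJa_dD / r
        if cfg.mode == "MAPD_WS":
            val -= cfg.lam * r / T
            grad[self.N * NX] += -cfg.lam / T
            grad[0] += cfg.lam / T
            if self.nd:
                grad[self.d_idx] += cfg.lam * r / T**2
        return val, grad

    @staticmethod
    def _quad_cost(V, h):
        """Integral of summed squares of piecewise-linear node signals and
        its gradient with respect to the node values."""
        v0, v1 = V[:-1], V[1:]
        val = float(np.sum(h[:, None] / 3.0 * (v0**2 + v0 * v1 + v1**2)))
        grad = np.zeros_like(V)
        grad[:-1] += h[:, None] / 3.0 * (2 * v0 + v1)
        grad[1:] += h[:, None] / 3.0 * (v0 + 2 * v1)
        return val, grad

    def _project_velocities(self, q, qd):
        """Project node velocities onto the active-contact null space.

        Removes the part of the guess velocities that would move active
        contact points, which otherwise dominates the initial defect and
        contact-velocity violations.
        """
        out = qd.copy()
        for k in range(q.shape[0]):
            phase = self.schedule[int(self.node_phase[min(k, self.N - 1)])]
            if not len(phase.contacts):
                continue
            kin = self.engine.kinematics(q[k][:, None], qd[k][:, None])
            _, Jc, _ = self.engine.contact_system(kin, phase.contacts)
            J = np.real(Jc[:, :, 0])
            JJt = J @ J.T
            try:
                out[k] = qd[k] - J.T @ np.linalg.solve(JJt, J @ qd[k])
            except np.linalg.LinAlgError:
                out[k] = qd[k] - J.T @ np.linalg.lstsq(JJt, J @ qd[k], rcond=None)[0]
        return out

    @staticmethod
    def _midpoint_consistent_rate(values, h):
        """Node derivatives v' satisfying the trapezoidal relations
        v_{k+1} - v_k = h_k/2 (v'_k + v'_{k+1}) exactly.

        The relations leave the initial derivative free (the recursion
        alternates sign); it is chosen to minimize the summed squared
        derivative norm.  For data generated by the same trapezoidal
        scheme this reconstructs the generating derivatives.
        """
        n = values.shape[0]
        rhs = 2.0 * np.diff(values, axis=0) / h[:, None]
        s = np.zeros_like(values)
        sign = np.ones(n)
        for k in range(n - 1):
            s[k + 1] = rhs[k] - s[k]
            sign[k + 1] = -sign[k]
        v0 = -(sign[:, None] * s).sum(axis=0) / n
        return sign[:, None] * v0 + s

    def _seed_activations(self, q, qd, qdd_target=None):
        """Activations minimizing the velocity defects of a kinematic guess.

        With the node kinematics fixed, the constrained accelerations are
        affine in the activation vector, so the trapezoidal velocity
        defects are linear in the activation sequence: the seed is the
        bounded linear least-squares solution (with a small effort
        regularizer resolving actuation redundancy).  If the guess
        kinematics are dynamically reachable, the generating activations
        are a feasible point of this system and the residual defects are
        essentially zero.
        """
        from scipy.optimize import lsq_linear

        n_nodes = q.shape[0]
        times = self.node_times(self.durations if self.durations is not None
                                else GUESS_PHASE_FRACTIONS
                                * self.config.stride_time_guess)
        h = np.diff(times)
        if qdd_target is None:
            qdd_target = (np.gradient(qd, times, axis=0) if n_nodes > 2
                          else np.zeros_like(qd))
        eng = self.engine

        # affine acceleration model per (node, owning phase): the defect of
        # interval k evaluates both endpoints under phase j(k), so boundary
        # nodes need one model per adjacent phase
        probe = np.zeros((NMUSCLES, NMUSCLES + 1))
        probe[:, 1:] = np.eye(NMUSCLES)
        model_cache = {}

        def affine(k, j):
            key = (k, j)
            if key not in model_cache:
                phase = self.schedule[j]
                qb = np.tile(q[k][:, None], (1, NMUSCLES + 1))
                qdb = np.tile(qd[k][:, None], (1, NMUSCLES + 1))
                kin = eng.kinematics(qb, qdb)
                Q = eng.generalized_actuation(qb, qdb, probe)
                try:
                    qdd, _, _ = eng.constrained_qdd(kin, Q, phase.contacts)
                    qdd = np.real(qdd)
                    model_cache[key] = (qdd[:, 0],
                                       qdd[:, 1:] - qdd[:, :1])
                except Exception:
                    model_cache[key] = (np.zeros(NDOF),
                                        np.zeros((NDOF, NMUSCLES)))
            return model_cache[key]

        # defect rows, linear in the stacked activation sequence
        import scipy.sparse as sps

        rows = []
        rhs = []
        for k in range(n_nodes - 1):
            j = int(self.node_phase[min(k, self.N - 1)])
            b0, G0 = affine(k, j)
            b1, G1 = affine(k + 1, j)
            lhs = sps.lil_matrix((NDOF, n_nodes * NMUSCLES))
            lhs[:, k * NMUSCLES:(k + 1) * NMUSCLES] = 0.5 * h[k] * G0
            lhs[:, (k + 1) * NMUSCLES:(k + 2) * NMUSCLES] = 0.5 * h[k] * G1
            rows.append(lhs)
            rhs.append(qd[k + 1] - qd[k] - 0.5 * h[k] * (b0 + b1))
        nvar = n_nodes * NMUSCLES
        reg_mag = 0.01 * sps.eye(nvar)
        smooth = sps.lil_matrix(((n_nodes - 1) * NMUSCLES, nvar))
        for k in range(n_nodes - 1):
            r = slice(k * NMUSCLES, (k + 1) * NMUSCLES)
            smooth[r, k * NMUSCLES:(k + 1) * NMUSCLES] = -0.15 * np.eye(NMUSCLES)
            smooth[r, (k + 1) * NMUSCLES:(k + 2) * NMUSCLES] = 0.15 * np.eye(NMUSCLES)
        A = sps.vstack(rows + [reg_mag, smooth]).toarray()
        y = np.concatenate(rhs + [np.zeros(nvar + (n_nodes - 1) * NMUSCLES)])
        res = lsq_linear(A, y, bounds=(0.0, 1.0), method="bvls",
                         max_iter=3 * nvar)
        return res.x.reshape(n_nodes, NMUSCLES)

    def _seed_excitations(self, act, times):
        """Excitations consistent with the activation trajectory.

        Inverts the (exact) activation rate law at each node for the
        midpoint-consistent activation derivative; where the required rate
        is unreachable the excitation saturates at its bound.
        """
        from .mtg import ActivationParams

        p = ActivationParams()
        adot = np.gradient(act, times, axis=0)
        c1 = 1.0 / p.tau_A - 1.0 / p.tau_D
        c2 = 1.0 / p.tau_D
        exc = np.empty_like(act)
        rising = adot >= 0
        # rising branch: (e - a)(c1 e + c2) = adot, take the upper root
        b = c2 - act * c1
        disc = b * b + 4.0 * c1 * (act * c2 + adot)
        exc_r = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * c1)
        exc_f = act + adot * p.tau_D
        exc[rising] = exc_r[rising]
        exc[~rising] = exc_f[~rising]
        return np.clip(exc, 0.0, 1.0)

    # -- objective Hessian ----------------------------------------------
    def objective_hess(self, z):
        """Exact (sparse) Hessian of the objective."""
        cfg = self.config
        H = sp.lil_matrix((self.nvar, self.nvar))
        X, U, D, P = self.unpack(z)
        times = self.node_times(D)
        h = np.diff(times)

        if cfg.mode == "LS":
            ref = self.reference
            idx = np.clip(np.searchsorted(times, ref.times, side="right") - 1,
                          0, self.N - 1)
            w = (ref.times - times[idx]) / h[idx]
            for m in range(ref.times.size):
                k = idx[m]
                for (ka, wa) in ((k, 1 - w[m]), (k + 1, w[m])):
                    for (kb, wb) in ((k, 1 - w[m]), (k + 1, w[m])):
                        r = slice(ka * NX, ka * NX + NDOF)
                        c = slice(kb * NX, kb * NX + NDOF)
                        H[r, c] = H[r, c] + sp.diags(2.0 * cfg.W * wa * wb)
            for k in range(self.N):
                u0, u1 = self.u_idx(k), self.u_idx(k + 1)
                d = cfg.delta * h[k] / 3.0
                eye = sp.eye(NMUSCLES)
                H[u0, u0] = H[u0, u0] + 2 * d * eye
                H[u1, u1] = H[u1, u1] + 2 * d * eye
                H[u0, u1] = H[u0, u1] + d * eye
                H[u1, u0] = H[u1, u0] + d * eye
            return H.tocsr()

        # MAPD / MAPD_WS: f = Ja(A, D)/r [- lam r/T]
        A = X[:, 2 * NDOF:]
        Ja, dJa_dA = self._quad_cost(A, h)
        v0, v1 = A[:-1], A[1:]
        per_interval = np.sum((v0**2 + v0 * v1 + v1**2) / 3.0, axis=1)
        dJa_dD = np.array([per_interval[self.node_phase[:self.N] == j].sum()
                           for j in range(_NPHASE)]) / self.npp
        r = X[self.N, 0] - X[0, 0]
        i_r0, i_rN = 0, self.N * NX     # pelvis-x columns
        a_off = 2 * NDOF

        def a_slice(k):
            return slice(k * NX + a_off, (k + 1) * NX)

        # d2Ja/dA2 / r  (block tridiagonal) and dA-dD cross terms
        for k in range(self.N):
            j = int(self.node_phase[k])
            hk = h[k]
            eye = sp.eye(NMUSCLES)
            s0, s1 = a_slice(k), a_slice(k + 1)
            H[s0, s0] = H[s0, s0] + (2 * hk / (3 * r)) * eye
            H[s1, s1] = H[s1, s1] + (2 * hk / (3 * r)) * eye
            H[s0, s1] = H[s0, s1] + (hk / (3 * r)) * eye
            H[s1, s0] = H[s1, s0] + (hk / (3 * r)) * eye
            if self.nd:
                col = self.nx_block + self.nu_block + j
                g0 = (2 * A[k] + A[k + 1]) / (3.0 * self.npp * r)
                g1 = (A[k] + 2 * A[k + 1]) / (3.0 * self.npp * r)
                H[s0, col] = H[s0, col] + g0[:, None]
                H[col, s0] = H[col, s0] + g0[None, :]
                H[s1, col] = H[s1, col] + g1[:, None]
                H[col, s1] = H[col, s1] + g1[None, :]

        # cross terms with r and the r-r curvature
        for k in range(self.N + 1):
            s = a_slice(k)
            gk = dJa_dA[k] / r**2
            H[s, i_rN] = H[s, i_rN] - gk[:, None]
            H[i_rN, s] = H[i_rN, s] - gk[None, :]
            H[s, i_r0] = H[s, i_r0] + gk[:, None]
            H[i_r0, s] = H[i_r0, s] + gk[None, :]
        if self.nd:
            for j in range(_NPHASE):
                col = self.nx_block + self.nu_block + j
                gd = dJa_dD[j] / r**2
                H[col, i_rN] -= gd
                H[i_rN, col] -= gd
                H[col, i_r0] += gd
                H[i_r0, col] += gd
        rr = 2.0 * Ja / r**3
        H[i_rN, i_rN] += rr
        H[i_r0, i_r0] += rr
        H[i_rN, i_r0] -= rr
        H[i_r0, i_rN] -= rr

        if cfg.mode == "MAPD_WS":
            T = float(np.sum(D))
            d_cols = list(range(self.nx_block + self.nu_block,
                                self.nx_block + self.nu_block + self.nd))
            lamT2 = cfg.lam / T**2
            for col in d_cols:
                H[i_rN, col] += lamT2
                H[col, i_rN] += lamT2
                H[i_r0, col] -= lamT2
                H[col, i_r0] -= lamT2
                for col2 in d_cols:
                    H[col, col2] -= 2.0 * cfg.lam * r / T**3
        return H.tocsr()

    # -- initial guess --------------------------------------------------
    def default_guess(self) -> np.ndarray:
        cfg = self.config
        n_nodes = self.N + 1
        qdd_seed = None
        consistent = False
        if cfg.mode == "LS" and cfg.initial_guess != "stance":
            times = self.node_times(self.durations)
            q = np.empty((n_nodes, NDOF))
            for c in range(NDOF):
                q[:, c] = np.interp(times, self.reference.times,
                                    self.reference.q_meas[:, c])
            # velocities consistent with the trapezoidal defects; fall
            # back to finite differences when the reconstruction blows up
            # (reference not generated by a comparable discretization)
            h = np.diff(times)
            qd_grad = np.gradient(q, times, axis=0)
            qd_cons = self._midpoint_consistent_rate(q, h)
            if np.max(np.abs(qd_cons)) < 3.0 * max(1.0, np.max(np.abs(qd_grad))):
                qd = qd_cons
                consistent = True
                qdd_seed = self._midpoint_consistent_rate(qd, h)
                qdd_grad = np.gradient(qd, times, axis=0)
                if np.max(np.abs(qdd_seed)) > 3.0 * np.max(np.abs(qdd_grad)) + 50.0:
                    qdd_seed = qdd_grad
            else:
                qd = qd_grad
        elif cfg.initial_guess == "stance":
            q, qd = _stance_guess(self.model, n_nodes, cfg.seed, cfg.guess_jitter)
            if cfg.mode != "LS":
                q[:, 0] += cfg.speed_guess * cfg.stride_time_guess * \
                    np.linspace(0, 1, n_nodes)
                qd[:, 0] = cfg.speed_guess
        else:
            if self.durations is not None:
                stride_t = float(np.sum(self.durations))
                frac = self.node_times(self.durations) / stride_t
            else:
                stride_t = cfg.stride_time_guess
                frac = np.concatenate(
                    [[0.0], np.cumsum(np.repeat(GUESS_PHASE_FRACTIONS / self.npp,
                                                self.npp))])
            braced = bool(self.engine.orthosis_profiles)
            q, qd = prototype_gait(self.model, stride_t, cfg.speed_guess,
                                   frac, seed=cfg.seed, jitter=cfg.guess_jitter,
                                   pitch_max=0.06 if braced else 0.25,
                                   ankle_range=0.08 if braced else 1.0)
        if not consistent:
            qd = self._project_velocities(q, qd)
        act = self._seed_activations(q, qd, qdd_seed)
        guess_times = self.node_times(
            self.durations if self.durations is not None
            else GUESS_PHASE_FRACTIONS * cfg.stride_time_guess)
        bounds = self.variable_bounds()
        X = np.concatenate([q, qd, act], axis=1)
        U = self._seed_excitations(act, guess_times)
        D = (GUESS_PHASE_FRACTIONS * cfg.stride_time_guess
             if self.free_durations else None)
        P = np.asarray(cfg.stiffness_guess) if self.npar else None
        z = self.pack(X, U, D, P)
        return np.clip(z, bounds.lb, bounds.ub)


# ----------------------------------------------------------------------
# public assembly / solve API
# ----------------------------------------------------------------------

def assemble_ocp(model: PlanarModel, mtgs: list[MTGParams],
                 orthosis_profiles: dict | None,
                 schedule: list[PhaseSpec], config: OCPConfig,
                 reference: ReferenceGait | None = None) -> GaitOCP:
    """Build the transcribed NLP for the requested mode."""
    return GaitOCP(model, mtgs, schedule, config,
                   orthosis_profiles=orthosis_profiles, reference=reference)


def solve_ocp(ocp: GaitOCP, initial_guess=None) -> Solution:
    """Solve the transcribed NLP and package the result.

    ``initial_guess`` may be None (mode-dependent default), a previous
    Solution (warm start) or a raw packed variable vector.  The solve is
    deterministic for identical guesses and settings.
    """
    cfg = ocp.config
    if initial_guess is None:
        z0 = ocp.default_guess()
        if cfg.mode == "LS":
            eq0, _, ineq0, _ = ocp._evaluate(z0)
            viol0 = max(float(np.max(np.abs(eq0))) if eq0.size else 0.0,
                        float(max(0.0, -np.min(ineq0))) if ineq0.size else 0.0)
            if viol0 > 5.0:
                # Gauss-Newton penalty pre-solve places the iterate close
                # to the feasible tracking manifold before the exact
                # solve; from a nearly feasible guess the interior point
                # alone converges and stays in the tracking valley
                z0 = solve_tracking_penalty(ocp, z0)
    elif isinstance(initial_guess, Solution):
        z0 = _warm_start_vector(ocp, initial_guess)
    else:
        z0 = np.asarray(initial_guess, dtype=float)
        if z0.shape != (ocp.nvar,):
            raise ValueError("initial guess has wrong dimension")
    bounds = ocp.variable_bounds()
    z0 = np.clip(z0, bounds.lb, bounds.ub)

    def eq_fun(z):
        return ocp._evaluate(z)[0]

    def eq_jac(z):
        return ocp._evaluate(z)[1]

    def ineq_fun(z):
        return ocp._evaluate(z)[2]

    def ineq_jac(z):
        return ocp._evaluate(z)[3]

    constraints = [
        NonlinearConstraint(eq_fun, 0.0, 0.0, jac=eq_jac),
        NonlinearConstraint(ineq_fun, 0.0, np.inf, jac=ineq_jac),
    ]
    res = None
    z_cur = z0
    prev_obj = math.inf
    for attempt in range(cfg.restarts + 1):
        res = minimize(ocp.objective, z_cur, jac=ocp.objective_grad,
                       hess=ocp.objective_hess,
                       bounds=bounds, constraints=constraints,
                       method="trust-constr",
                       options=dict(maxiter=cfg.maxiter, gtol=cfg.gtol,
                                    xtol=cfg.xtol, verbose=cfg.verbose,
                                    initial_tr_radius=1.0))
        z_cur = np.clip(res.x, bounds.lb, bounds.ub)
        # a warm restart resets the barrier; repeat while it keeps paying
        if res.status in (1, 2):
            break
        if prev_obj - res.fun < 1e-3 * max(1.0, abs(res.fun)):
            break
        prev_obj = res.fun
    z_final = z_cur
    eq, _, ineq, _ = ocp._evaluate(z_final)
    viol = max(float(np.max(np.abs(eq))) if eq.size else 0.0,
               float(max(0.0, -np.min(ineq))) if ineq.size else 0.0)
    if viol > cfg.feas_tol:
        # Gauss-Newton projection onto the constraint manifold; leaves the
        # objective essentially unchanged when the violation is small
        z_polished = refine_feasibility(ocp, z_final)
        eq2, _, ineq2, _ = ocp._evaluate(z_polished)
        viol2 = max(float(np.max(np.abs(eq2))) if eq2.size else 0.0,
                    float(max(0.0, -np.min(ineq2))) if ineq2.size else 0.0)
        if viol2 < viol:
            z_final = z_polished
    return _package_solution(ocp, z_final, res)


def _warm_start_vector(ocp: GaitOCP, sol: Solution) -> np.ndarray:
    # map per phase: the source state at the same phase-local fraction
    # seeds each target node, so phase boundaries (and, for matching node
    # counts and durations, every node) correspond exactly
    src_start = sol.phase_start_times()
    times_old = sol.times
    times_new = np.empty(ocp.N + 1)
    for k in range(ocp.N + 1):
        j = min(k // ocp.npp, _NPHASE - 1)
        frac = (k - j * ocp.npp) / ocp.npp
        times_new[k] = src_start[j] + frac * sol.durations[j]
    X = np.empty((ocp.N + 1, NX))
    U = np.empty((ocp.N + 1, NMUSCLES))
    for c in range(NX):
        X[:, c] = np.interp(times_new, times_old, sol.states[:, c])
    for c in range(NMUSCLES):
        U[:, c] = np.interp(times_new, times_old, sol.controls[:, c])
    D = sol.durations if ocp.free_durations else None
    if ocp.npar:
        P = (sol.stiffness if sol.stiffness is not None
             else np.asarray(ocp.config.stiffness_guess))
    else:
        P = None
    return ocp.pack(X, U, D, P)


def _package_solution(ocp: GaitOCP, z: np.ndarray, res) -> Solution:
    X, U, D, P = ocp.unpack(z)
    eq, _, ineq, _ = ocp._evaluate(z)
    viol = max(float(np.max(np.abs(eq))) if eq.size else 0.0,
               float(max(0.0, -np.min(ineq))) if ineq.size else 0.0)
    grf_nodes = []
    for k in range(ocp.N + 1):
        j = int(ocp.node_phase[min(k, ocp.N - 1)])
        phase = ocp.schedule[j]
        if len(phase.contacts):
            lam, rows = ocp.engine.node_forces(
                X[k][:, None], U[k][:, None], phase.contacts,
                stiffness=(P[:, None] if P is not None else None))
            grf_nodes.append((rows, np.real(lam[:, 0]).copy()))
        else:
            grf_nodes.append(([], np.zeros(0)))
    objective = ocp.objective(z)
    sol = Solution(
        times=ocp.node_times(D), states=X.copy(), controls=U.copy(),
        durations=np.asarray(D, dtype=float).copy(),
        objective=float(objective),
        mode=ocp.config.mode,
        stiffness=(np.asarray(P, dtype=float).copy() if P is not None else None),
        status=str(getattr(res, "message", "")),
        success=bool(np.isfinite(objective)) and viol < ocp.config.feas_tol,
        constr_violation=viol,
        grf_nodes=grf_nodes,
        node_phase=ocp.node_phase.copy(),
    )
    return sol


def solve_tracking_penalty(ocp: GaitOCP, z0=None,
                           penalties=(1e2, 1e4, 1e6),
                           grf_hinge: bool = True,
                           max_nfev: int = 60,
                           hinge_eps: float = 1e-4) -> np.ndarray:
    """Gauss-Newton penalty solve of a tracking problem.

    The tracking objective, the control regularization, the dynamics
    defects (as quadratic penalties of increasing weight) and smoothed
    hinge penalties of the inequality rows form one nonlinear
    least-squares residual, minimized with scipy's bounded
    trust-region-reflective solver using the exact sparse Jacobians.
    Because all residuals vanish (or are tiny) at a feasible tracking
    solution, Gauss-Newton converges far faster here than a
    general-purpose NLP method; the returned point is then suitable as a
    warm start for the exactly-constrained solve.
    """
    from scipy.optimize import least_squares

    cfg = ocp.config
    if cfg.mode != "LS":
        raise ValueError("penalty tracking requires an LS-mode transcription")
    if z0 is None:
        z0 = ocp.default_guess()
    bounds = ocp.variable_bounds()
    lb, ub = bounds.lb.copy(), bounds.ub.copy()
    pinned = lb >= ub              # the TRF solver needs strict inequality
    lb[pinned] -= 1e-9
    ub[pinned] += 1e-9
    z0 = np.clip(z0, lb + 1e-12, ub - 1e-12)
    ref = ocp.reference
    times = ocp.node_times(ocp.durations)
    h = np.diff(times)

    # linear tracking block: rows map z to q(t_m) - q_m
    idx = np.clip(np.searchsorted(times, ref.times, side="right") - 1,
                  0, ocp.N - 1)
    w = (ref.times - times[idx]) / h[idx]
    sqw = np.sqrt(cfg.W)
    rows, cols, vals, y = [], [], [], []
    rr = 0
    for m in range(ref.times.size):
        k = idx[m]
        for c in range(NDOF):
            rows += [rr, rr]
            cols += [k * NX + c, (k + 1) * NX + c]
            vals += [sqw[c] * (1 - w[m]), sqw[c] * w[m]]
            y.append(sqw[c] * ref.q_meas[m, c])
            rr += 1
    # trapezoid-weighted control regularization rows
    u_weight = np.zeros(ocp.N + 1)
    u_weight[:-1] += h / 2.0
    u_weight[1:] += h / 2.0
    for k in range(ocp.N + 1):
        sw = math.sqrt(cfg.delta * u_weight[k])
        for c in range(NMUSCLES):
            rows.append(rr)
            cols.append(ocp.nx_block + k * NMUSCLES + c)
            vals.append(sw)
            y.append(0.0)
            rr += 1
    T_lin = sp.csr_matrix((vals, (rows, cols)), shape=(rr, ocp.nvar))
    y = np.asarray(y)

    z = z0
    for rho in penalties:
        sr = math.sqrt(rho)

        def fun(zv):
            eq, _, ineq, _ = ocp._evaluate(zv)
            parts = [T_lin @ zv - y, sr * eq]
            if grf_hinge and ineq.size:
                s = -ineq
                parts.append(sr * 0.5 * (s + np.sqrt(s * s + hinge_eps**2)))
            return np.concatenate(parts)

        def jac(zv):
            eq, Jeq, ineq, Jineq = ocp._evaluate(zv)
            parts = [T_lin, sr * Jeq]
            if grf_hinge and ineq.size:
                s = -ineq
                dh = -0.5 * (1.0 + s / np.sqrt(s * s + hinge_eps**2))
                parts.append(sp.diags(sr * dh) @ Jineq)
            return sp.vstack(parts).tocsr()

        res = least_squares(fun, z, jac=jac, bounds=(lb, ub),
                            method="trf", tr_solver="lsmr",
                            max_nfev=max_nfev, xtol=1e-12, ftol=1e-10,
                            gtol=1e-12)
        z = res.x
    return z


def refine_feasibility(ocp: GaitOCP, z: np.ndarray,
                       penalties=(1e4, 1e6, 1e8), prox_weight: float = 1.0,
                       max_nfev: int = 30, hinge_eps: float = 1e-6) -> np.ndarray:
    """Project an almost-feasible iterate onto the constraint manifold.

    Minimizes the distance to ``z`` plus heavily weighted squared
    constraint residuals (smoothed hinge for the inequalities) by
    Gauss-Newton.  Used as a final polish after the interior-point solve:
    the projection distance is of the order of the remaining violation, so
    the objective value is essentially unchanged while the violation drops
    to solver-tolerance level.
    """
    from scipy.optimize import least_squares

    bounds = ocp.variable_bounds()
    lb, ub = bounds.lb.copy(), bounds.ub.copy()
    pinned = lb >= ub
    lb[pinned] -= 1e-9
    ub[pinned] += 1e-9
    z_ref = np.clip(z, lb + 1e-12, ub - 1e-12)
    prox = sp.eye(ocp.nvar, format="csr") * prox_weight
    zc = z_ref
    for rho in penalties:
        sr = math.sqrt(rho)

        def fun(zv):
            eq, _, ineq, _ = ocp._evaluate(zv)
            s = -ineq
            hinge = 0.5 * (s + np.sqrt(s * s + hinge_eps**2))
            return np.concatenate([prox_weight * (zv - z_ref), sr * eq,
                                   sr * hinge])

        def jac(zv):
            eq, Jeq, ineq, Jineq = ocp._evaluate(zv)
            s = -ineq
            dh = -0.5 * (1.0 + s / np.sqrt(s * s + hinge_eps**2))
            return sp.vstack([prox, sr * Jeq,
                              sp.diags(sr * dh) @ Jineq]).tocsr()

        res = least_squares(fun, zc, jac=jac, bounds=(lb, ub), method="trf",
                            tr_solver="lsmr", max_nfev=max_nfev,
                            xtol=1e-14, ftol=1e-12, gtol=1e-14)
        zc = res.x
    return zc


def prototype_reference(model: PlanarModel, config: OCPConfig) -> ReferenceGait:
    """Kinematic prototype packaged as a tracking reference."""
    D = GUESS_PHASE_FRACTIONS * config.stride_time_guess
    T = float(D.sum())
    times = np.linspace(0.0, T, 2 * config.n_shooting + 1)
    q, _ = prototype_gait(model, T, config.speed_guess, times / T,
                          seed=config.seed)
    return ReferenceGait(times=times, q_meas=q, durations=D)


def solve_walking(model: PlanarModel, mtgs: list[MTGParams],
                  orthosis_profiles: dict | None, config: OCPConfig,
                  warm_start: Solution | None = None) -> Solution:
    """Staged solve of a gait synthesis problem (MAPD / MAPD_WS).

    Synthesis from scratch is a hard nonconvex problem; a dynamic tracking
    fit of the kinematic walking prototype (fixed phase durations) is
    solved first and warm-starts the requested objective.  Pass a previous
    Solution as ``warm_start`` to skip the tracking stage.
    """
    schedule = default_phase_schedule()
    if config.mode == "LS":
        raise ValueError("solve_walking is for the synthesis modes; "
                         "use assemble_ocp/solve_ocp for LS tracking")
    if warm_start is None:
        # dynamically feasible periodic tracking of the kinematic walking
        # prototype provides the warm start for the synthesis objective
        ref = prototype_reference(model, config)
        cfg_t = replace(config, mode="LS", fixed_durations=ref.durations,
                        free_stiffness=False, enforce_periodicity=True,
                        maxiter=min(config.maxiter, 300), restarts=1)
        ocp_t = assemble_ocp(model, mtgs, orthosis_profiles, schedule, cfg_t,
                             reference=ref)
        warm_start = solve_ocp(ocp_t)
    ocp2 = assemble_ocp(model, mtgs, orthosis_profiles, schedule, config)
    return solve_ocp(ocp2, warm_start)


def identify_orthosis_stiffness(model: PlanarModel, mtgs: list[MTGParams],
                                orthosis_params: dict, config: OCPConfig,
                                reference: ReferenceGait | None = None,
                                initial_guess=None):
    """Identify the free orthosis springs (K_D, K_P per side).

    ``orthosis_params`` maps side -> OrthosisParams whose K_D/K_P entries
    serve as the initial guess.  Returns ``(stiffness dict, Solution)``
    with stiffness keyed ``(side, 'K_D'|'K_P')``.
    """
    from .orthosis import build_profile

    profiles = {s: build_profile(p) for s, p in orthosis_params.items()}
    config = replace(config) if not isinstance(config, OCPConfig) else config
    config.free_stiffness = True
    config.stiffness_guess = (
        orthosis_params["L"].K_D, orthosis_params["L"].K_P,
        orthosis_params["R"].K_D, orthosis_params["R"].K_P)
    ocp = assemble_ocp(model, mtgs, profiles, default_phase_schedule(),
                       config, reference=reference)
    sol = solve_ocp(ocp, initial_guess)
    kd_l, kp_l, kd_r, kp_r = sol.stiffness
    out = {("L", "K_D"): float(kd_l), ("L", "K_P"): float(kp_l),
           ("R", "K_D"): float(kd_r), ("R", "K_P"): float(kp_r)}
    return out, sol
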