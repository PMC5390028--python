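"""Evaluation of simulated gait: metrics, RMS comparisons, torque-angle
profiles, and the stiffness perturbation analysis.

Conventions: reports use clinical angle signs (hip flexion positive, knee
flexion positive, ankle plantarflexion positive) in degrees; stride
normalization is 0-100% of the full left-right cycle.  Step length is the
anterior distance between the two heels at the stepping foot's touchdown;
duty factor is the fraction of the stride a foot spends between its heel
strike and its toe off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import ANKLE_CLINICAL_SIGN, JOINT_COORD, DynamicsEngine
from .model import NDOF, PlanarModel
from .ocp import (GaitOCP, OCPConfig, Solution, assemble_ocp,
                  default_phase_schedule, solve_ocp)

__all__ = ["GaitMetrics", "PerturbationReport", "gait_metrics",
           "rms_difference", "net_ankle_torque_profile", "perturb_parameters",
           "clinical_angles"]

#: sign per generalized rotational coordinate mapping to clinical
#: convention (flexion/plantarflexion positive in reports)
_CLINICAL_SIGNS = np.array([1.0, 1.0, 1.0, 1.0,     # pelvis x/z/rot, torso
                            1.0, -1.0, -1.0,        # hip, knee, ankle (L)
                            1.0, -1.0, -1.0])       # hip, knee, ankle (R)

# phase indices (0-based) delimiting stance per side in the 8-phase stride
_L_STANCE_START = 2     # left heel strike opens phase 3
_R_STANCE_END = 4       # right toe off opens phase 5
_R_STANCE_START = 6     # right heel strike opens phase 7


def clinical_angles(q: np.ndarray) -> np.ndarray:
    """Generalized coordinates mapped to clinical signs (radians)."""
    return np.asarray(q) * _CLINICAL_SIGNS


@dataclass(frozen=True)
class GaitMetrics:
    """Spatiotemporal and posture metrics of one stride."""

    step_length_l: float          # m
    step_length_r: float          # m
    walking_speed: float          # m/s
    min_knee_angle_stance_l: float   # deg, knee flexion
    min_knee_angle_stance_r: float   # deg
    duty_factor_l: float
    duty_factor_r: float
    objective: float

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in (
            "step_length_l", "step_length_r", "walking_speed",
            "min_knee_angle_stance_l", "min_knee_angle_stance_r",
            "duty_factor_l", "duty_factor_r", "objective")}


def _heel_positions(model: PlanarModel, q: np.ndarray) -> dict:
    from .dynamics import contact_kinematics

    ck = contact_kinematics(model, q, np.zeros(NDOF))
    return {side: ck[f"{side}_heel"][0] for side in ("L", "R")}


def gait_metrics(sol: Solution, model: PlanarModel,
                 n_samples: int = 200) -> GaitMetrics:
    """Stride metrics of a gait solution.

    Touchdown events are read from the phase schedule: left heel strike at
    the start of phase 3, right heel strike at the start of phase 7.
    """
    if sol.durations.size != 8:
        raise ValueError("solution must carry the 8 phase durations")
    nu = sol.phase_start_times()
    T = sol.T
    if T <= 0:
        raise ValueError("non-positive stride time; no touchdown events found")

    # step lengths at the touchdown instants
    q_lhs = sol.interp_states(nu[_L_STANCE_START])[0, :NDOF]
    q_rhs = sol.interp_states(nu[_R_STANCE_START])[0, :NDOF]
    heels_l = _heel_positions(model, q_lhs)
    heels_r = _heel_positions(model, q_rhs)
    step_l = float(heels_l["L"][0] - heels_l["R"][0])
    step_r = float(heels_r["R"][0] - heels_r["L"][0])

    # minimum knee flexion during stance, per side
    ts = np.linspace(0.0, T, n_samples)
    qs = sol.interp_states(ts)[:, :NDOF]
    knee_flex_l = np.degrees(-qs[:, 5])
    knee_flex_r = np.degrees(-qs[:, 8])
    in_l_stance = ts >= nu[_L_STANCE_START]
    in_r_stance = (ts <= nu[_R_STANCE_END]) | (ts >= nu[_R_STANCE_START])
    min_knee_l = float(np.min(knee_flex_l[in_l_stance]))
    min_knee_r = float(np.min(knee_flex_r[in_r_stance]))

    duty_l = float((T - nu[_L_STANCE_START]) / T)
    duty_r = float((nu[_R_STANCE_END] + (T - nu[_R_STANCE_START])) / T)

    return GaitMetrics(
        step_length_l=step_l, step_length_r=step_r,
        walking_speed=sol.walking_speed,
        min_knee_angle_stance_l=min_knee_l,
        min_knee_angle_stance_r=min_knee_r,
        duty_factor_l=duty_l, duty_factor_r=duty_r,
        objective=float(sol.objective),
    )


def rms_difference(times_a, values_a, times_b, values_b,
                   n_grid: int = 101, degrees: bool = False) -> np.ndarray:
    """Per-channel RMS difference on a common stride-normalized grid.

    Both trajectories are resampled (linear interpolation) to ``n_grid``
    points over their own 0-100% stride before differencing; channels are
    the trailing axis.  With ``degrees`` the result is converted from
    radians.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    va = np.atleast_2d(np.asarray(values_a, dtype=float))
    vb = np.atleast_2d(np.asarray(values_b, dtype=float))
    if va.shape[0] != ta.size or vb.shape[0] != tb.size:
        raise ValueError("times and values lengths differ")
    if va.shape[1] != vb.shape[1]:
        raise ValueError("channel counts differ")
    if ta.size < 2 or tb.size < 2:
        raise ValueError("empty overlap: need at least two samples each")
    grid = np.linspace(0.0, 1.0, n_grid)
    sa = (ta - ta[0]) / (ta[-1] - ta[0])
    sb = (tb - tb[0]) / (tb[-1] - tb[0])
    out = np.empty(va.shape[1])
    for c in range(va.shape[1]):
        ra = np.interp(grid, sa, va[:, c])
        rb = np.interp(grid, sb, vb[:, c])
        d = ra - rb
        out[c] = np.sqrt(np.mean(d * d))
    return np.degrees(out) if degrees else out


def net_ankle_torque_profile(sol: Solution, model: PlanarModel,
                             mtgs, orthosis_profile=None, side: str = "L",
                             n_samples: int = 200):
    """Net ankle torque vs clinical ankle angle over that side's stance.

    The net torque is the summed extension + flexion MTG torque plus the
    orthosis contribution (if any) - the quantity an inverse dynamics
    analysis of the braced leg would report.  Returns (angles rad, torques
    Nm, secant slope Nm/rad); slope from a least-squares line fit over the
    stance samples.
    """
    from .mtg import mtg_torque

    nu = sol.phase_start_times()
    T = sol.T
    if side == "L":
        windows = [(nu[_L_STANCE_START], T)]
    else:
        windows = [(0.0, nu[_R_STANCE_END]), (nu[_R_STANCE_START], T)]
    ts = np.concatenate([np.linspace(a, b, max(8, int(n_samples * (b - a) / T)))
                         for a, b in windows if b > a])
    states = sol.interp_states(ts)
    ci = JOINT_COORD[("ankle", side)]
    q_ankle = states[:, ci]
    qd_ankle = states[:, NDOF + ci]
    theta_clin = ANKLE_CLINICAL_SIGN * q_ankle

    torque = np.zeros_like(q_ankle)
    for i, p in enumerate(mtgs):
        if p.joint == "ankle" and p.side == side:
            act = states[:, 2 * NDOF + i]
            tq = mtg_torque(p, act, q_ankle, qd_ankle)
            torque += ANKLE_CLINICAL_SIGN * np.asarray(tq)
    if orthosis_profile is not None:
        torque += np.asarray(orthosis_profile.torque(theta_clin))

    span = np.ptp(theta_clin)
    slope = (float(np.polyfit(theta_clin, torque, 1)[0])
             if span > 1e-9 else float("nan"))
    return theta_clin, torque, slope


@dataclass
class PerturbationReport:
    """Sensitivity of cost and gait metrics to orthosis spring changes."""

    base_metrics: GaitMetrics
    rows: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


_PERTURBABLE = (("L", "K_D"), ("L", "K_P"), ("R", "K_D"), ("R", "K_P"))


def perturb_parameters(model: PlanarModel, mtgs, orthosis_params: dict,
                       config: OCPConfig, base_sol: Solution,
                       rel_perturbation: float = -0.05,
                       params=_PERTURBABLE,
                       resolve_base: bool = True) -> PerturbationReport:
    """Re-solve the gait OCP with each orthosis spring perturbed.

    Each listed parameter is scaled by ``1 + rel_perturbation`` (default
    -5%), held fixed (not re-identified), and the OCP is re-solved warm-
    started from the base solution.  With ``resolve_base`` (default) the
    unperturbed problem is first re-solved under exactly the same
    protocol and its result replaces the raw base: both sides of every
    percent change then receive identical additional optimization, so the
    reported changes isolate the parameter effect (and a zero
    perturbation yields exactly zero rows).  Rows report percent changes
    of the objective, minimum stance knee angles, step lengths and
    walking speed; for near-zero baselines the absolute change is
    reported alongside.  Non-converged re-solves are flagged, never
    fabricated.
    """
    from .orthosis import build_profile

    cfg = replace(config, free_stiffness=False)
    schedule = default_phase_schedule()
    if resolve_base:
        profiles = {s: build_profile(p) for s, p in orthosis_params.items()}
        ocp0 = assemble_ocp(model, mtgs, profiles, schedule, cfg)
        base_resolved = solve_ocp(ocp0, base_sol)
        if base_resolved.success:
            base_sol = base_resolved
    base_metrics = gait_metrics(base_sol, model)
    report = PerturbationReport(base_metrics=base_metrics)

    for side, name in params:
        pert_params = dict(orthosis_params)
        pert_params[side] = replace(
            orthosis_params[side],
            **{name: getattr(orthosis_params[side], name) * (1.0 + rel_perturbation)})
        profiles = {s: build_profile(p) for s, p in pert_params.items()}
        ocp = assemble_ocp(model, mtgs, profiles, schedule, cfg)
        sol = solve_ocp(ocp, base_sol)
        # a re-solve counts as usable when its violation is physically
        # negligible, even if it missed the strict solver tolerance
        usable = sol.constr_violation < 1e-5 and np.isfinite(sol.objective)
        row = {"parameter": f"{side} {name}",
               "perturbation": rel_perturbation,
               "converged": bool(usable),
               "violation": float(sol.constr_violation)}
        if usable:
            metrics = gait_metrics(sol, model)
            for key, label in (("objective", "phi"),
                               ("min_knee_angle_stance_l", "min_knee_l"),
                               ("min_knee_angle_stance_r", "min_knee_r"),
                               ("step_length_l", "step_length_l"),
                               ("step_length_r", "step_length_r"),
                               ("walking_speed", "walking_speed")):
                base = getattr(base_metrics, key)
                new = getattr(metrics, key)
                denom = abs(base)
                row[f"{label}_pct"] = (100.0 * (new - base) / denom
                                       if denom > 1e-9 else float("nan"))
                if denom <= 1.0 and "knee" in label:
                    row[f"{label}_abs"] = new - base
        report.rows.append(row)
    return report
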