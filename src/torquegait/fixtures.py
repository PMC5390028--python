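"""Deterministic synthetic gait fixtures.

No recorded patient data ships with the package; every consumer of
reference gaits (tracking fits, stiffness identification, evaluation
reports) is exercised against synthetic strides generated here by the
production optimal control pipeline at reduced node counts.  All
randomness is derived from the fixture seed, so identical specs reproduce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import build_default_model
from .mtg import build_mtg_set, default_strength_table
from .ocp import OCPConfig, ReferenceGait, Solution, solve_walking
from .orthosis import attach_orthosis, build_profile, default_orthosis_params

__all__ = ["FixtureSpec", "generate_reference_gait", "add_measurement_noise",
           "make_recovery_fixture", "fixture_problem"]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of one synthetic gait experiment."""

    total_mass: float = 24.7       # kg
    height: float = 1.25           # m
    population: str = "pathological"
    with_orthosis: bool = False
    true_stiffness: dict | None = None   # side -> (K_D, K_P), for recovery
    joint_noise_deg: float = 0.0
    grf_noise_n: float = 0.0
    seed: int = 0
    stride_time: float = 1.1       # s
    speed_guess: float = 0.5       # m/s
    n_shooting: int = 16
    maxiter: int = 400
    kin_rate: float = 120.0        # Hz, exported kinematic sampling
    grf_rate: float = 1080.0       # Hz, exported force sampling
    mode: str = "MAPD"

    def __post_init__(self) -> None:
        if self.joint_noise_deg < 0 or self.grf_noise_n < 0:
            raise ValueError("noise levels must be non-negative")
        if self.total_mass <= 0 or self.height <= 0:
            raise ValueError("invalid anthropometry")


def fixture_problem(spec: FixtureSpec):
    """Model, MTG set, orthosis profiles and OCP config for a spec."""
    model = build_default_model(spec.total_mass, spec.height)
    strengths = default_strength_table(spec.population)
    mtgs = build_mtg_set(strengths)
    profiles = None
    orthosis_params = None
    if spec.with_orthosis or spec.true_stiffness:
        orthosis_params = {}
        for side in ("L", "R"):
            p = default_orthosis_params(side)
            if spec.true_stiffness and side in spec.true_stiffness:
                kd, kp = spec.true_stiffness[side]
                p = replace(p, K_D=float(kd), K_P=float(kp))
            orthosis_params[side] = p
        model = attach_orthosis(model, orthosis_params["L"], orthosis_params["R"])
        profiles = {s: build_profile(p) for s, p in orthosis_params.items()}
    config = OCPConfig(mode=spec.mode, n_shooting=spec.n_shooting,
                       stride_time_guess=spec.stride_time,
                       speed_guess=spec.speed_guess, seed=spec.seed,
                       maxiter=spec.maxiter)
    return model, mtgs, profiles, orthosis_params, config


def _export_reference(sol: Solution, model, engine_parts, spec: FixtureSpec) -> ReferenceGait:
    """Sample a solved stride at the export rates.

    Ground reactions are evaluated at the collocation nodes under each
    interval's contact set and interpolated linearly in between; since
    unilaterality and the friction cone are convex and hold at the nodes,
    the exported force samples inherit them exactly.
    """
    from .dynamics import contact_kinematics

    T = sol.T
    n_kin = max(8, int(round(spec.kin_rate * T)))
    times = np.linspace(0.0, T, n_kin)
    q = sol.interp_states(times)[:, :10]

    if not sol.grf_nodes:
        return ReferenceGait(times=times, q_meas=q,
                             durations=sol.durations.copy())

    # per-node foot forces from the constrained node multipliers (which
    # satisfy unilaterality and the friction cone); linear interpolation
    # of these convex-cone points inherits both properties exactly
    n_nodes = sol.states.shape[0]
    node_f = {side: np.zeros((n_nodes, 3)) for side in ("L", "R")}
    for k, (rows, lam) in enumerate(sol.grf_nodes):
        ck = contact_kinematics(model, sol.states[k, :10],
                                sol.states[k, 10:20])
        for side in ("L", "R"):
            fz = fx = mom = 0.0
            for (point, comp), val in zip(rows, lam):
                if not point.startswith(side):
                    continue
                if comp == "z":
                    fz += val
                    mom += val * ck[point][0][0]
                else:
                    fx += val
            node_f[side][k] = (fx, fz, mom / fz if fz > 1e-9 else 0.0)

    n_grf = max(16, int(round(spec.grf_rate * T)))
    t_grf = np.linspace(0.0, T, n_grf)
    grf = {}
    for side in ("L", "R"):
        arr = np.column_stack([np.interp(t_grf, sol.times, node_f[side][:, c])
                               for c in range(3)])
        arr[arr[:, 1] <= 1e-9] = 0.0
        grf[side] = arr
    return ReferenceGait(times=times, q_meas=q,
                         durations=sol.durations.copy(),
                         grf={"times": t_grf, **grf})


def generate_reference_gait(spec: FixtureSpec, solution: Solution | None = None):
    """Synthesize a feasible stride and export it as a reference recording.

    The stride is produced by the production OCP (staged prototype ->
    tracking -> synthesis solve) at the spec's reduced node count; the
    generating Solution is returned alongside as ground truth.  A stride
    already synthesized under the spec's conditions may be passed as
    ``solution`` to reuse it for export instead of re-solving.
    """
    model, mtgs, profiles, _, config = fixture_problem(spec)
    sol = solution if solution is not None else solve_walking(
        model, mtgs, profiles, config)
    if not sol.success:
        raise RuntimeError(
            f"coarse gait synthesis failed (violation "
            f"{sol.constr_violation:.2e}, status: {sol.status})")
    ref = _export_reference(sol, model, (mtgs, profiles), spec)
    if spec.joint_noise_deg or spec.grf_noise_n:
        ref = add_measurement_noise(ref, spec)
    return ref, sol


def add_measurement_noise(ref: ReferenceGait, spec: FixtureSpec) -> ReferenceGait:
    """Seeded i.i.d. Gaussian noise on joint angles and force channels."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5E5]))
    q = ref.q_meas.copy()
    sigma_q = np.radians(spec.joint_noise_deg)
    if sigma_q > 0:
        # angular channels only; pelvis translations stay clean
        q[:, 2:] += rng.normal(0.0, sigma_q, size=q[:, 2:].shape)
    grf = dict(ref.grf)
    if spec.grf_noise_n > 0 and grf:
        for side in ("L", "R"):
            if side in grf:
                arr = np.asarray(grf[side]).copy()
                arr[:, :2] += rng.normal(0.0, spec.grf_noise_n,
                                         size=arr[:, :2].shape)
                grf[side] = arr
    return ReferenceGait(times=ref.times.copy(), q_meas=q,
                         durations=ref.durations.copy(), grf=grf)


def make_recovery_fixture(spec: FixtureSpec, solution: Solution | None = None):
    """Observed gait for stiffness identification plus a blinded truth record.

    The stride is synthesized with the orthosis springs at the spec's true
    values; the exported observation carries kinematics/forces only - the
    truth (true stiffness and generating solution) is returned separately
    and never written into the observed data.
    """
    if not spec.true_stiffness:
        raise ValueError("recovery fixture needs true_stiffness values")
    ref, sol = generate_reference_gait(
        replace(spec, with_orthosis=True), solution=solution)
    truth = {"stiffness": {s: tuple(map(float, v))
                           for s, v in spec.true_stiffness.items()},
             "solution": sol}
    return ref, truth
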