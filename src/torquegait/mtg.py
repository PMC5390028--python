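"""Muscle torque generators (MTGs) and excitation-activation dynamics.

Each actuated rotational degree of freedom (hips, knees, ankles, torso) is
driven by an agonist-antagonist pair of lumped torque actuators.  An MTG
produces joint torque

    tau = tau_max * a * fA(theta) * fV(omega)

where ``a`` is the muscle activation, ``fA`` the normalized active
torque-angle curve (unit peak at ``theta_peak``), and ``fV`` the normalized
torque-angular-velocity curve (``fV(0) = 1``, decreasing with shortening
velocity, eccentric plateau above one).  Only active torque components are
modeled; passive musculotendon torques are out of scope.

Activation follows a first-order excitation-activation lag with distinct
activation/deactivation time constants (0.011 s and 0.068 s).  The exact
law has a non-smooth branch switch at ``e = a``; a tanh-blended variant with
a configurable half-width is provided for derivative-based optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .curves import NormalizedCurve, fit_c2_bezier

__all__ = [
    "JOINTS", "MTG_ORDER", "MTGParams", "ActivationParams", "StrengthTable",
    "FLEXION_EXTENSION_RATIOS", "default_strength_table", "default_curves",
    "mtg_torque", "calibrate_tau_max", "flexion_from_extension",
    "torso_strength_from_hips", "activation_rate", "smoothed_activation_rate",
    "build_mtg_set",
]

JOINTS = ("torso", "hip", "knee", "ankle")

#: Canonical actuator ordering: one (extension, flexion) pair per actuated
#: coordinate, coordinate order (torso, hip_l, knee_l, ankle_l, hip_r,
#: knee_r, ankle_r).  14 MTGs total.
MTG_ORDER = tuple(
    (joint, side, direction)
    for joint, side in (
        ("torso", None),
        ("hip", "L"), ("knee", "L"), ("ankle", "L"),
        ("hip", "R"), ("knee", "R"), ("ankle", "R"),
    )
    for direction in ("extension", "flexion")
)

# Sign mapping from muscle pull direction to the generalized-coordinate
# convention (rotations positive counter-clockwise seen from the model's
# right; ankle "extension" is plantarflexion, i.e. push-off).
_SIGNS = {
    ("torso", "extension"): -1.0, ("torso", "flexion"): +1.0,
    ("hip", "extension"): -1.0, ("hip", "flexion"): +1.0,
    ("knee", "extension"): +1.0, ("knee", "flexion"): -1.0,
    ("ankle", "extension"): -1.0, ("ankle", "flexion"): +1.0,
}

#: Flexion/extension strength ratios per joint, derived from the healthy
#: strength columns of the bundled reference table; the same ratios hold in
#: the pathological columns to within rounding.
FLEXION_EXTENSION_RATIOS = {
    "hip": 34.27 / 48.82,
    "knee": 19.26 / 36.08,
    "ankle": 13.71 / 39.46,
    "torso": 34.27 / 48.82,
}

# Maximum isometric joint torques (Nm): age/weight-matched healthy child and
# the pathological case the default model emulates.
_STRENGTHS = {
    "healthy": {
        ("hip", "L", "extension"): 48.82, ("hip", "R", "extension"): 48.82,
        ("hip", "L", "flexion"): 34.27, ("hip", "R", "flexion"): 34.27,
        ("knee", "L", "extension"): 36.08, ("knee", "R", "extension"): 36.08,
        ("knee", "L", "flexion"): 19.26, ("knee", "R", "flexion"): 19.26,
        ("ankle", "L", "extension"): 39.46, ("ankle", "R", "extension"): 39.46,
        ("ankle", "L", "flexion"): 13.71, ("ankle", "R", "flexion"): 13.71,
        ("torso", None, "extension"): 48.82, ("torso", None, "flexion"): 34.27,
    },
    "pathological": {
        ("hip", "L", "extension"): 30.35, ("hip", "R", "extension"): 18.64,
        ("hip", "L", "flexion"): 21.31, ("hip", "R", "flexion"): 13.08,
        ("knee", "L", "extension"): 24.55, ("knee", "R", "extension"): 22.40,
        ("knee", "L", "flexion"): 13.10, ("knee", "R", "flexion"): 11.95,
        ("ankle", "L", "extension"): 16.84, ("ankle", "R", "extension"): 32.32,
        ("ankle", "L", "flexion"): 5.85, ("ankle", "R", "flexion"): 11.23,
        ("torso", None, "extension"): 24.49, ("torso", None, "flexion"): 17.19,
    },
}


@dataclass(frozen=True)
class ActivationParams:
    """Activation/deactivation time constants of the first-order lag (s)."""

    tau_A: float = 0.011
    tau_D: float = 0.068

    def __post_init__(self) -> None:
        if self.tau_A <= 0 or self.tau_D <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_A >= self.tau_D:
            raise ValueError("activation must be faster than deactivation")


@dataclass(frozen=True)
class MTGParams:
    """One lumped muscle torque generator."""

    joint: str
    side: str | None
    direction: str
    tau_max: float
    fA: NormalizedCurve
    fV: NormalizedCurve
    sign: float
    theta_peak: float = 0.0

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.direction not in ("extension", "flexion"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.tau_max <= 0:
            raise ValueError("tau_max must be positive")
        if self.sign not in (-1.0, 1.0):
            raise ValueError("sign must be +/-1")


@dataclass(frozen=True)
class StrengthTable:
    """Maximum isometric torques per (joint, side, direction)."""

    entries: dict
    population: str = "custom"

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if value <= 0:
                raise ValueError(f"non-positive strength for {key}")

    def get(self, joint: str, side: str | None, direction: str) -> float:
        key = (joint, None if joint == "torso" else side, direction)
        if key not in self.entries:
            raise KeyError(f"no strength entry for {key}")
        return float(self.entries[key])

    def to_frame(self):
        import pandas as pd

        rows = [
            {"joint": j, "side": s or "", "direction": d,
             "tau_max": v, "population": self.population}
            for (j, s, d), v in sorted(self.entries.items(),
                                       key=lambda kv: (kv[0][0], str(kv[0][1]), kv[0][2]))
        ]
        return pd.DataFrame(rows)


def default_strength_table(population: str = "pathological") -> StrengthTable:
    """Bundled strength table for the healthy or pathological default model."""
    if population not in _STRENGTHS:
        raise ValueError(f"unknown population {population!r}")
    return StrengthTable(dict(_STRENGTHS[population]), population=population)


# ----------------------------------------------------------------------
# normalized characteristic curves
# ----------------------------------------------------------------------

#: Angular velocity (rad/s) at which concentric torque vanishes.
OMEGA_MAX_DEFAULT = 12.0
#: Eccentric plateau of the torque-velocity curve.
ECCENTRIC_PLATEAU = 1.4
#: Hill curvature constant of the concentric branch.
_HILL_GAMMA = 3.0
#: Width (rad) of the bell-shaped active torque-angle curve; places the
#: half-torque point ~43 deg off peak, matching the falloff of
#: experimental joint torque-angle data.
_FA_WIDTH = 0.9


@lru_cache(maxsize=8)
def default_curves(omega_max: float = OMEGA_MAX_DEFAULT) -> tuple[NormalizedCurve, NormalizedCurve]:
    """Bundled C2 torque-angle and torque-velocity curves.

    fA is a bell with unit peak at zero muscle angle.  fV follows a Hill
    hyperbola on the concentric side (zero torque at ``omega_max``) and a
    saturating eccentric branch with slope matched at zero, approaching a
    plateau of 1.4.  Both are least-squares Bezier fits, rescaled so that
    the normalization identities fA(0) = fV(0) = 1 hold exactly.
    """
    th = np.linspace(-np.pi, np.pi, 201)
    fa_target = np.exp(-((th / _FA_WIDTH) ** 2))
    fa = fit_c2_bezier(th, fa_target, n_spans=10)
    fa = fa.scaled(1.0 / float(fa(0.0)))

    om = np.linspace(-omega_max, omega_max, 241)
    fv_target = np.empty_like(om)
    con = om >= 0
    fv_target[con] = (omega_max - om[con]) / (omega_max + _HILL_GAMMA * om[con])
    b = ECCENTRIC_PLATEAU - 1.0
    half = b * omega_max / (1.0 + _HILL_GAMMA)  # matches the concentric slope at 0
    u = -om[~con]
    fv_target[~con] = 1.0 + b * u / (u + half)
    fv = fit_c2_bezier(om, fv_target, n_spans=12)
    fv = fv.scaled(1.0 / float(fv(0.0)))
    return fa, fv


def _shift(curve: NormalizedCurve, dx: float) -> NormalizedCurve:
    return NormalizedCurve(curve.breakpoints + dx, curve.control.copy())


def build_mtg_set(strengths: StrengthTable | None = None,
                  curves: tuple[NormalizedCurve, NormalizedCurve] | None = None,
                  theta_peaks: dict | None = None) -> list[MTGParams]:
    """All 14 MTGs in canonical order for a given strength table."""
    strengths = strengths or default_strength_table()
    fa0, fv = curves or default_curves()
    theta_peaks = theta_peaks or {}
    mtgs = []
    for joint, side, direction in MTG_ORDER:
        peak = float(theta_peaks.get((joint, side, direction), 0.0))
        fa = _shift(fa0, peak) if peak else fa0
        mtgs.append(MTGParams(
            joint=joint, side=side, direction=direction,
            tau_max=strengths.get(joint, side, direction),
            fA=fa, fV=fv, sign=_SIGNS[(joint, direction)],
            theta_peak=peak,
        ))
    return mtgs


# ----------------------------------------------------------------------
# torque evaluation and calibration
# ----------------------------------------------------------------------

def mtg_torque(p: MTGParams, a, theta, omega):
    """Joint torque (Nm) of one MTG at activation ``a``, joint angle
    ``theta`` (rad) and joint velocity ``omega`` (rad/s).

    The joint state is mapped into the muscle convention through the
    actuator sign (positive muscle angle/velocity = motion in the muscle's
    pull direction); the resulting torque is mapped back the same way.
    """
    a_arr = np.asarray(a)
    if np.any(np.real(a_arr) < -1e-12) or np.any(np.real(a_arr) > 1.0 + 1e-12):
        raise ValueError("activation must lie in [0, 1]")
    theta_m = p.sign * np.asarray(theta)
    omega_m = p.sign * np.asarray(omega)
    return p.sign * p.tau_max * a_arr * p.fA(theta_m) * p.fV(omega_m)


def calibrate_tau_max(theta_at_peak: float, omega_at_peak: float,
                      tau_peak_observed: float, a_assumed: float = 0.9,
                      curves: tuple[NormalizedCurve, NormalizedCurve] | None = None) -> float:
    """Maximum isometric torque consistent with an observed peak torque.

    Inverts the MTG torque law at the (muscle-frame) angle and velocity
    where the peak extension torque was observed, assuming the subject was
    activating at ``a_assumed`` of maximum (default 90%).
    """
    if tau_peak_observed <= 0:
        raise ValueError("observed peak torque must be positive")
    if not 0 < a_assumed <= 1:
        raise ValueError("a_assumed must lie in (0, 1]")
    fa, fv = curves or default_curves()
    product = float(fa(theta_at_peak)) * float(fv(omega_at_peak))
    if product <= 1e-9:
        raise ValueError("characteristic-curve product vanishes at the given "
                         "point; the peak lies outside feasible curve support")
    return tau_peak_observed / (a_assumed * product)


def flexion_from_extension(tau_ext: float, joint: str) -> float:
    """Maximum flexion torque from the extension value via the bundled
    per-joint flexion/extension ratio."""
    if joint not in FLEXION_EXTENSION_RATIOS:
        raise ValueError(f"unknown joint {joint!r}")
    if tau_ext <= 0:
        raise ValueError("extension torque must be positive")
    return tau_ext * FLEXION_EXTENSION_RATIOS[joint]


def torso_strength_from_hips(strengths: StrengthTable) -> tuple[float, float]:
    """Torso (extension, flexion) strength as the mean of the two hips."""
    ext = 0.5 * (strengths.get("hip", "L", "extension")
                 + strengths.get("hip", "R", "extension"))
    flex = 0.5 * (strengths.get("hip", "L", "flexion")
                  + strengths.get("hip", "R", "flexion"))
    return ext, flex


# ----------------------------------------------------------------------
# excitation-activation dynamics
# ----------------------------------------------------------------------

def activation_rate(e, a, p: ActivationParams = ActivationParams()):
    """da/dt of the exact (branch-switching) activation law."""
    e_arr = np.asarray(e, dtype=float)
    a_arr = np.asarray(a, dtype=float)
    if np.any(e_arr < -1e-12) or np.any(e_arr > 1 + 1e-12):
        raise ValueError("excitation must lie in [0, 1]")
    if np.any(a_arr < -1e-12) or np.any(a_arr > 1 + 1e-12):
        raise ValueError("activation must lie in [0, 1]")
    rising = (e_arr - a_arr) * (e_arr / p.tau_A + (1.0 - e_arr) / p.tau_D)
    falling = (e_arr - a_arr) / p.tau_D
    out = np.where(e_arr >= a_arr, rising, falling)
    return float(out) if out.ndim == 0 else out


def smoothed_activation_rate(e, a, p: ActivationParams = ActivationParams(),
                             width: float = 1e-3):
    """C-infinity blend of the two activation branches over ``2*width``.

    Required by derivative-based OCP solvers; coincides with the exact law
    away from the switching manifold e = a.  Complex-step safe.
    """
    e_arr = np.asarray(e)
    a_arr = np.asarray(a)
    s = 0.5 * (1.0 + np.tanh((e_arr - a_arr) / width))
    rising_gain = e_arr / p.tau_A + (1.0 - e_arr) / p.tau_D
    gain = s * rising_gain + (1.0 - s) / p.tau_D
    return (e_arr - a_arr) * gain
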