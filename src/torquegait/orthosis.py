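"""Parametrized ankle-foot orthosis (AFO).

The orthosis is a spring-loaded ankle joint between carbon-fiber shank and
foot shells.  Its restoring torque as a function of the clinical ankle
angle (plantarflexion positive, dorsiflexion negative) follows a 5-stage
law: a small preload plateau of +/- tau_0 inside a window of half-width
theta_W around the neutral offset theta_0; linear springs K_D (dorsiflexion
side) and K_P (plantarflexion side) between the window edges and the hard
stops theta_DH / theta_PH; and the much stiffer frame-flexing slopes K_DH /
K_PH beyond the hard stops.  Stage corners are blended with quintic spans
over a small half-width so the profile is C2, as required by the
derivative-based optimal control solver.

K_D and K_P are the clinically adjustable springs and enter the profile
affinely, so a profile built once exposes exact torque values for any
candidate (K_D, K_P) without re-smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curves import NormalizedCurve
from .model import PlanarModel

__all__ = ["OrthosisParams", "OrthosisProfile", "build_profile",
           "orthosis_torque", "attach_orthosis", "default_orthosis_params"]

#: Hard-stop angles and plantarflexion hard stop differ slightly between
#: the two sides of the reference device; all angles in radians.
_SIDE_DEFAULTS = {
    "L": dict(theta_DH=-0.12, theta_PH=0.09),
    "R": dict(theta_DH=-0.13, theta_PH=0.10),
}


@dataclass(frozen=True)
class OrthosisParams:
    """Torque-angle parameters of one orthosis plus its added masses."""

    side: str
    K_DH: float = 200.0       # Nm/rad, dorsiflexion hard-stop stiffness
    theta_DH: float = -0.12   # rad, dorsiflexion hard stop
    K_D: float = 55.0         # Nm/rad, dorsiflexion spring (free parameter)
    theta_0: float = -0.02    # rad, torque-free offset
    theta_W: float = 0.01     # rad, preload window half-width
    tau_0: float = 1.0        # Nm, preload magnitude
    K_P: float = 5.0          # Nm/rad, plantarflexion spring (free parameter)
    theta_PH: float = 0.09    # rad, plantarflexion hard stop
    K_PH: float = 200.0       # Nm/rad, plantarflexion hard-stop stiffness
    shank_added_mass: float = 0.34  # kg
    foot_added_mass: float = 0.69   # kg (includes the shoe)

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if min(self.K_DH, self.K_D, self.K_P, self.K_PH) < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.theta_W <= 0:
            raise ValueError("theta_W must be positive")
        if not (self.theta_DH < self.theta_0 - self.theta_W
                < self.theta_0 + self.theta_W < self.theta_PH):
            raise ValueError("angle parameters must satisfy "
                             "theta_DH < theta_0 - theta_W < theta_0 + theta_W < theta_PH")
        if min(self.shank_added_mass, self.foot_added_mass) < 0:
            raise ValueError("added masses must be non-negative")


def default_orthosis_params(side: str, **changes) -> OrthosisParams:
    """Reference device parameters for one side."""
    base = dict(_SIDE_DEFAULTS[side])
    base.update(changes)
    return OrthosisParams(side=side, **base)


def _staged_curve(p: OrthosisParams, K_D: float, K_P: float,
                  extension: float = 0.1) -> NormalizedCurve:
    """C2 profile for explicit spring values via quintic Hermite spans."""
    thL = p.theta_0 - p.theta_W
    thR = p.theta_0 + p.theta_W
    w = min(0.005, 0.25 * p.theta_W)

    def line(theta):
        """Unsmoothed staged torque and slope at one angle."""
        if theta < p.theta_DH:
            v = p.tau_0 + K_D * (thL - p.theta_DH) + p.K_DH * (p.theta_DH - theta)
            return v, -p.K_DH
        if theta < thL:
            return p.tau_0 + K_D * (thL - theta), -K_D
        if theta < p.theta_0:
            return p.tau_0, 0.0
        if theta < thR:
            return -p.tau_0, 0.0
        if theta < p.theta_PH:
            return -p.tau_0 - K_P * (theta - thR), -K_P
        v = -p.tau_0 - K_P * (p.theta_PH - thR) - p.K_PH * (theta - p.theta_PH)
        return v, -p.K_PH

    junctions = [p.theta_DH, thL, p.theta_0, thR, p.theta_PH]
    bp = [p.theta_DH - extension]
    for j in junctions:
        bp.extend([j - w, j + w])
    bp.append(p.theta_PH + extension)
    bp = np.array(bp)
    if np.any(np.diff(bp) <= 0):
        raise ValueError("stage junctions too close for the smoothing width")

    vals, slopes = zip(*(line(x) for x in bp))
    # evaluate each breakpoint on its own side of the nearest junction
    vals = list(vals)
    slopes = list(slopes)
    for i, x in enumerate(bp):
        v, s = line(x + (1e-12 if i % 2 == 1 else -1e-12) if 0 < i < bp.size - 1 else x)
        vals[i], slopes[i] = v, s
    curv = np.zeros_like(bp)
    return NormalizedCurve.from_hermite_segments(bp, vals, slopes, curv)


@dataclass(frozen=True)
class OrthosisProfile:
    """Smoothed torque-angle profile, affine in the free springs.

    ``torque(theta)`` evaluates at the parameters the profile was built
    from; ``torque(theta, K_D=..., K_P=...)`` evaluates the same smoothed
    family at other spring values (exactly, since the staged construction
    is affine in K_D and K_P).
    """

    params: OrthosisParams
    curve: NormalizedCurve
    _base: NormalizedCurve
    _dKD: NormalizedCurve
    _dKP: NormalizedCurve

    def torque(self, theta, K_D=None, K_P=None, deriv: int = 0):
        if K_D is None and K_P is None:
            return self.curve(theta, deriv=deriv)
        kd = self.params.K_D if K_D is None else K_D
        kp = self.params.K_P if K_P is None else K_P
        return (self._base(theta, deriv=deriv)
                + kd * self._dKD(theta, deriv=deriv)
                + kp * self._dKP(theta, deriv=deriv))

    def with_stiffness(self, K_D: float, K_P: float) -> "OrthosisProfile":
        return build_profile(replace(self.params, K_D=float(K_D), K_P=float(K_P)))


def build_profile(p: OrthosisParams) -> OrthosisProfile:
    """Build the C2 torque-angle profile for one orthosis.

    Rebuilding with identical parameters is bit-identical (pure function of
    the parameter values).
    """
    base = _staged_curve(p, 0.0, 0.0)
    only_kd = _staged_curve(p, 1.0, 0.0)
    only_kp = _staged_curve(p, 0.0, 1.0)
    dKD = NormalizedCurve(base.breakpoints, only_kd.control - base.control)
    dKP = NormalizedCurve(base.breakpoints, only_kp.control - base.control)
    curve = NormalizedCurve(base.breakpoints,
                            base.control + p.K_D * dKD.control + p.K_P * dKP.control)
    return OrthosisProfile(params=p, curve=curve, _base=base, _dKD=dKD, _dKP=dKP)


def orthosis_torque(profile: OrthosisProfile, theta_ankle):
    """Orthosis torque (Nm) at a clinical ankle angle (rad).

    Linear extrapolation with the hard-stop slopes applies beyond the
    profile domain.
    """
    return profile.torque(theta_ankle)


def attach_orthosis(model: PlanarModel, left: OrthosisParams,
                    right: OrthosisParams,
                    attachment_offsets: dict | None = None) -> PlanarModel:
    """Model with the orthosis masses added to the shank and foot segments.

    Added mass defaults to the segment center of mass (device geometry is
    not resolved), leaving the center of mass and inertia unchanged;
    ``attachment_offsets`` may map segment name to an attachment position
    (m from the proximal joint along the segment axis) instead.
    """
    attachment_offsets = attachment_offsets or {}
    out = model
    for params in (left, right):
        side = params.side.lower()
        for seg_key, dm in ((f"shank_{side}", params.shank_added_mass),
                            (f"foot_{side}", params.foot_added_mass)):
            if dm == 0:
                continue
            seg = out.segment(seg_key)
            r = attachment_offsets.get(seg_key, seg.com_offset)
            m_new = seg.mass + dm
            com_new = (seg.mass * seg.com_offset + dm * r) / m_new
            inertia_new = (seg.inertia_com
                           + seg.mass * (seg.com_offset - com_new) ** 2
                           + dm * (r - com_new) ** 2)
            out = out.with_segment(seg_key, mass=m_new, com_offset=com_new,
                                   inertia_com=inertia_new)
    return out
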