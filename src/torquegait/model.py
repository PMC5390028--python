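"""Planar 8-segment musculoskeletal model: anthropometry and containers.

The skeleton is a branched floating-base chain in the sagittal plane:
pelvis (2 translational DoFs + 1 rotation), a lumped torso/head/arms
segment, and per side a thigh, shank and flat foot.  10 generalized
coordinates total; 7 actuated rotational joints (torso, hips, knees,
ankles).  X is anterior, Z vertical, rotations positive counter-clockwise
viewed from the model's right, all joint angles zero in upright standing.

Segment masses, lengths, centers of mass and gyration radii default to a
bundled table of child anthropometric proportions (documented in the
package methods note, overridable per segment), scaled by total body mass
and height.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SegmentSpec", "PlanarModel", "ModelState", "ContactSet", "GroundReaction",
    "AnthropometryError", "build_default_model", "SEGMENT_NAMES",
    "COORD_NAMES", "CONTACT_POINTS", "CHILD_PROPORTIONS", "NDOF", "NMUSCLES",
]

NDOF = 10
NMUSCLES = 14

SEGMENT_NAMES = ("pelvis", "torso", "thigh_l", "shank_l", "foot_l",
                 "thigh_r", "shank_r", "foot_r")

COORD_NAMES = ("pelvis_x", "pelvis_z", "pelvis_rot", "torso", "hip_l",
               "knee_l", "ankle_l", "hip_r", "knee_r", "ankle_r")

CONTACT_POINTS = ("L_heel", "L_toe", "R_heel", "R_toe")

#: Child segment proportions: mass as a fraction of body mass, length and
#: ankle height as fractions of stature, center of mass as a fraction of
#: segment length from the proximal joint, radius of gyration about the
#: center of mass as a fraction of segment length.  The torso entry (which
#: lumps trunk, head and arms) absorbs the mass remainder so that segment
#: masses always sum to total body mass.
CHILD_PROPORTIONS = {
    "pelvis": dict(mass=0.140, length=0.090, com=0.50, gyration=0.31),
    "torso": dict(mass=None, length=0.400, com=0.50, gyration=0.45),
    "thigh": dict(mass=0.100, length=0.245, com=0.433, gyration=0.323),
    "shank": dict(mass=0.045, length=0.246, com=0.433, gyration=0.302),
    "foot": dict(mass=0.020, length=0.152, com=0.25, gyration=0.475),
}

#: Ankle joint height above the sole, fraction of stature.
ANKLE_HEIGHT_FRACTION = 0.039
#: Horizontal position of the ankle along the foot, fraction of foot length
#: from the heel.
ANKLE_FOOT_POSITION = 0.25


class AnthropometryError(ValueError):
    """Raised for physically invalid anthropometric input."""


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment: geometry and inertial properties."""

    name: str
    length: float        # m
    mass: float          # kg
    com_offset: float    # m from the proximal joint along the segment axis
    inertia_com: float   # kg m^2 about the center of mass

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.length <= 0:
            raise AnthropometryError(f"{self.name}: mass and length must be positive")
        if self.inertia_com < 0:
            raise AnthropometryError(f"{self.name}: inertia must be non-negative")
        if not 0.0 <= self.com_offset <= self.length:
            raise AnthropometryError(f"{self.name}: com_offset outside [0, length]")


@dataclass(frozen=True)
class PlanarModel:
    """Branched planar floating-base model with flat two-point feet.

    ``contact_points`` holds the heel/toe coordinates in each foot frame
    (origin at the ankle, x toward the toe in the neutral pose).
    """

    segments: dict
    gravity: float = 9.81
    contact_points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in SEGMENT_NAMES if n not in self.segments]
        if missing:
            raise AnthropometryError(f"missing segments: {missing}")
        if self.gravity <= 0:
            raise AnthropometryError("gravity must be positive (downward)")
        for point in CONTACT_POINTS:
            if point not in self.contact_points:
                raise AnthropometryError(f"missing contact point {point}")

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments.values()))

    @property
    def ndof(self) -> int:
        return NDOF

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[name]

    def with_segment(self, name: str, **changes) -> "PlanarModel":
        segs = dict(self.segments)
        segs[name] = replace(segs[name], **changes)
        return replace(self, segments=segs)


@dataclass(frozen=True)
class ModelState:
    """Generalized coordinates/velocities plus the 14 muscle activations."""

    q: np.ndarray
    qdot: np.ndarray
    act: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        qd = np.asarray(self.qdot, dtype=float)
        a = np.asarray(self.act, dtype=float)
        if q.shape != (NDOF,) or qd.shape != (NDOF,):
            raise ValueError(f"q and qdot must have shape ({NDOF},)")
        if a.shape != (NMUSCLES,):
            raise ValueError(f"act must have shape ({NMUSCLES},)")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd)) and np.all(np.isfinite(a))):
            raise ValueError("state entries must be finite")
        if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
            raise ValueError("activations must lie in [0, 1]")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "qdot", qd)
        object.__setattr__(self, "act", a)

    @staticmethod
    def zeros() -> "ModelState":
        return ModelState(np.zeros(NDOF), np.zeros(NDOF), np.zeros(NMUSCLES))


@dataclass(frozen=True)
class ContactSet:
    """Subset of the four foot-ground contact points that are active."""

    active: frozenset

    def __init__(self, active=()):
        pts = frozenset(active)
        unknown = pts - set(CONTACT_POINTS)
        if unknown:
            raise ValueError(f"unknown contact points {sorted(unknown)}")
        object.__setattr__(self, "active", pts)

    def __contains__(self, point: str) -> bool:
        return point in self.active

    def __iter__(self):
        return iter(sorted(self.active))

    def __len__(self) -> int:
        return len(self.active)

    def foot_points(self, side: str) -> tuple[str, ...]:
        return tuple(p for p in (f"{side}_heel", f"{side}_toe") if p in self.active)

    def is_flat(self, side: str) -> bool:
        """A foot is flat iff both its heel and toe contacts are active."""
        return len(self.foot_points(side)) == 2

    @property
    def feet(self) -> tuple[str, ...]:
        return tuple(s for s in ("L", "R") if self.foot_points(s))


@dataclass(frozen=True)
class GroundReaction:
    """Constraint forces at the active contacts.

    Vertical force is resolved per contact point; the anterior-posterior
    force of a flat foot is carried by a single anchor point and reported
    per foot (a rigid flat foot admits no unique heel/toe split of the
    shear force).
    """

    fz: dict      # point name -> N (upward)
    fx: dict      # side ("L"/"R") -> N (anterior)

    def foot_fz(self, side: str) -> float:
        return float(sum(v for k, v in self.fz.items() if k.startswith(side)))

    @property
    def total_fz(self) -> float:
        return float(sum(self.fz.values()))

    @property
    def total_fx(self) -> float:
        return float(sum(self.fx.values()))


def build_default_model(total_mass: float, height: float,
                        overrides: dict | None = None,
                        gravity: float = 9.81,
                        contact_fraction: float = 1.0) -> PlanarModel:
    """Default model from total mass (kg) and stature (m).

    ``overrides`` maps segment name to a dict of SegmentSpec field values
    replacing the regression-based defaults (e.g. patient-specific segment
    lengths).  ``contact_fraction`` scales the heel-to-toe distance relative
    to foot length.
    """
    if total_mass <= 0 or height <= 0:
        raise AnthropometryError("total mass and height must be positive")
    if not 0 < contact_fraction <= 1.5:
        raise AnthropometryError("contact_fraction must lie in (0, 1.5]")
    overrides = overrides or {}

    used_mass = sum(p["mass"] for key, p in CHILD_PROPORTIONS.items()
                    if p["mass"] is not None
                    for _ in (("",) if key in ("pelvis", "torso") else ("l", "r")))
    torso_fraction = 1.0 - used_mass
    if torso_fraction <= 0:
        raise AnthropometryError("segment mass fractions exceed unity")

    segments = {}
    for name in SEGMENT_NAMES:
        key = name.split("_")[0]
        prop = CHILD_PROPORTIONS[key]
        frac = torso_fraction if key == "torso" else prop["mass"]
        mass = frac * total_mass
        length = prop["length"] * height
        com = prop["com"] * length
        inertia = mass * (prop["gyration"] * length) ** 2
        spec = dict(name=name, length=length, mass=mass,
                    com_offset=com, inertia_com=inertia)
        spec.update(overrides.get(name, {}))
        segments[name] = SegmentSpec(**spec)

    foot_len = segments["foot_l"].length
    ankle_h = ANKLE_HEIGHT_FRACTION * height
    heel_x = -ANKLE_FOOT_POSITION * foot_len * contact_fraction
    toe_x = (1.0 - ANKLE_FOOT_POSITION) * foot_len * contact_fraction
    contact_points = {}
    for side, flen in (("L", segments["foot_l"].length), ("R", segments["foot_r"].length)):
        scale = flen / foot_len
        contact_points[f"{side}_heel"] = (heel_x * scale, -ankle_h)
        contact_points[f"{side}_toe"] = (toe_x * scale, -ankle_h)

    return PlanarModel(segments=segments, gravity=gravity,
                       contact_points=contact_points)


def standing_height_of_pelvis(model: PlanarModel, side: str = "L") -> float:
    """Pelvis (hip) height above ground in the neutral upright pose."""
    side = side.lower()
    ankle_h = -model.contact_points[f"{side.upper()}_heel"][1]
    return (model.segment(f"thigh_{side}").length
            + model.segment(f"shank_{side}").length + ankle_h)
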