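"""Rigid jaw geometry: domain types, the geometry file format, validation,
bilateral mirroring, and gape rotation about the quadrate-articular hinge.

Coordinate convention (right-handed, millimetres):

* ``+x`` anterior (toward the snout)
* ``+y`` toward the animal's left
* ``+z`` dorsal

Muscle cross-sectional areas are carried in cm² so that a muscle stress in
N/cm² yields forces in newtons directly. The jaw joint is idealised as a
single hinge through both quadrate-articular joint centers; gape is the
rotation of the mandible about that axis away from the closed pose, in the
sense that moves the jaw tip ventrally.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Point3",
    "MuscleBundle",
    "BitePoint",
    "JawModel",
    "GeometryError",
    "ValidationError",
    "MUSCLE_GROUPS",
    "SIDES",
    "BITE_POINT_LABELS",
    "load_jaw_model",
    "write_jaw_model",
    "validate_jaw_model",
    "joint_axis",
    "mirror_unilateral",
    "rotate_about_axis",
    "opening_sense",
    "open_jaw",
]

#: Recognised adductor groups (external complex, the two internal groups,
#: and the posterior adductor of the quadrate region).
MUSCLE_GROUPS = (
    "external_adductor",
    "pseudotemporalis",
    "pterygoideus",
    "posterior_adductor",
)

SIDES = ("left", "right")

#: Tooth-row bite points, anterior to posterior.
BITE_POINT_LABELS = (
    "jaw_tip",
    "anterior_caniniform",
    "posterior_caniniform",
    "posterior_most",
)

_AXIS_TOL = 1e-9
_UNIT_TOL = 1e-8


class GeometryError(ValueError):
    """Invalid geometry or an operation applied to unsuitable geometry."""


class ValidationError(GeometryError):
    """One or more model invariants violated; ``failures`` lists them all."""

    def __init__(self, failures: Sequence[str]):
        self.failures = list(failures)
        super().__init__("invalid jaw model:\n  - " + "\n  - ".join(self.failures))


@dataclass(frozen=True)
class Point3:
    """A point in the skull frame, millimetres."""

    x: float
    y: float
    z: float

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "Point3":
        x, y, z = (float(v) for v in a)
        return cls(x, y, z)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.to_array())))


@dataclass(frozen=True)
class MuscleBundle:
    """One adductor bundle modelled as a straight line of action.

    ``origin`` lies on the cranium (fixed during gape rotation), ``insertion``
    on the mandible (rotates with gape). ``acsa`` is the cross-sectional area
    in cm²; with no pennation correction the anatomical and physiological
    areas coincide, so a single field carries both. ``volume`` (cm³) and
    ``fiber_length`` (cm) are optional architecture metadata; consistency of
    acsa with volume/fiber_length is deliberately not enforced because areas
    may be measured directly from virtual dissection.
    """

    name: str
    group: str
    side: str
    origin: Point3
    insertion: Point3
    acsa: float
    volume: float | None = None
    fiber_length: float | None = None


@dataclass(frozen=True)
class BitePoint:
    label: str
    position: Point3


@dataclass(frozen=True)
class JawModel:
    """Rigid cranium/mandible landmark set with hinge joints, adductor
    bundles and tooth-row bite points.

    ``gape_reference_deg`` records the gape of the digitized pose (0 =
    closed). ``extra`` preserves unknown top-level keys of the geometry file
    across a load/write round-trip.
    """

    joint_left: Point3
    joint_right: Point3
    muscles: tuple[MuscleBundle, ...]
    bite_points: tuple[BitePoint, ...]
    gape_reference_deg: float = 0.0
    extra: dict = field(default_factory=dict)

    def bite_point(self, label: str) -> BitePoint:
        for bp in self.bite_points:
            if bp.label == label:
                return bp
        raise GeometryError(f"no bite point labelled {label!r}")

    def sides_present(self) -> set[str]:
        return {m.side for m in self.muscles}


# ---------------------------------------------------------------------------
# validation

def _dist_to_axis(p: np.ndarray, center: np.ndarray, axis: np.ndarray) -> float:
    r = p - center
    return float(np.linalg.norm(r - np.dot(r, axis) * axis))


def validate_jaw_model(model: JawModel) -> None:
    """Check every model invariant; raise :class:`ValidationError` listing
    all failures at once."""
    failures: list[str] = []

    for name, pt in (("joint_left", model.joint_left), ("joint_right", model.joint_right)):
        if not pt.is_finite():
            failures.append(f"{name}: coordinates must be finite")
    jl, jr = model.joint_left.to_array(), model.joint_right.to_array()
    axis_ok = np.linalg.norm(jl - jr) > _AXIS_TOL
    if not axis_ok:
        failures.append("joint_left and joint_right coincide (degenerate hinge axis)")

    if not model.muscles:
        failures.append("model must contain at least one muscle bundle")
    for i, m in enumerate(model.muscles):
        where = f"muscles[{i}] ({m.name!r})"
        if m.group not in MUSCLE_GROUPS:
            failures.append(f"{where}: group {m.group!r} not one of {MUSCLE_GROUPS}")
        if m.side not in SIDES:
            failures.append(f"{where}: side {m.side!r} not one of {SIDES}")
        if not (m.origin.is_finite() and m.insertion.is_finite()):
            failures.append(f"{where}: origin/insertion coordinates must be finite")
        if not (np.isfinite(m.acsa) and m.acsa > 0):
            failures.append(f"{where}: acsa must be > 0, got {m.acsa}")
        if np.allclose(m.origin.to_array(), m.insertion.to_array()):
            failures.append(f"{where}: origin equals insertion (zero-length line of action)")
        if m.volume is not None and m.volume <= 0:
            failures.append(f"{where}: volume must be > 0 when given")
        if m.fiber_length is not None and m.fiber_length <= 0:
            failures.append(f"{where}: fiber_length must be > 0 when given")

    if not model.bite_points:
        failures.append("model must contain at least one bite point")
    labels = [bp.label for bp in model.bite_points]
    if len(set(labels)) != len(labels):
        failures.append(f"bite point labels not unique: {labels}")
    for i, bp in enumerate(model.bite_points):
        where = f"bite_points[{i}] ({bp.label!r})"
        if bp.label not in BITE_POINT_LABELS:
            failures.append(f"{where}: label not one of {BITE_POINT_LABELS}")
        if not bp.position.is_finite():
            failures.append(f"{where}: position must be finite")
        elif axis_ok:
            center = (jl + jr) / 2.0
            axis = (jl - jr) / np.linalg.norm(jl - jr)
            if _dist_to_axis(bp.position.to_array(), center, axis) < _AXIS_TOL:
                failures.append(f"{where}: bite point lies on the joint axis")

    if not (np.isfinite(model.gape_reference_deg) and 0 <= model.gape_reference_deg < 90):
        failures.append(
            f"gape_reference_deg must lie in [0, 90), got {model.gape_reference_deg}"
        )

    if failures:
        raise ValidationError(failures)


# ---------------------------------------------------------------------------
# geometry file (JSON)

_LENGTH_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}
_AREA_TO_CM2 = {"cm2": 1.0, "mm2": 0.01, "m2": 1e4}
_KNOWN_KEYS = {"units", "joints", "gape_reference_deg", "muscles", "bite_points"}


def _point(raw, where: str, scale: float) -> Point3:
    if not (isinstance(raw, (list, tuple)) and len(raw) == 3):
        raise GeometryError(f"{where}: expected [x, y, z], got {raw!r}")
    try:
        return Point3(*(float(v) * scale for v in raw))
    except (TypeError, ValueError) as exc:
        raise GeometryError(f"{where}: non-numeric coordinate ({exc})") from None


def load_jaw_model(path) -> JawModel:
    """Read and fully validate a geometry JSON file.

    Lengths are converted to mm and areas to cm² from the file's ``units``
    block. Schema errors name the offending field; invariant violations are
    collected into a single :class:`ValidationError`.
    """
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise GeometryError("geometry file: top level must be a JSON object")

    units = data.get("units", {"length": "mm", "area": "cm2"})
    lu = units.get("length", "mm")
    au = units.get("area", "cm2")
    if lu not in _LENGTH_TO_MM:
        raise GeometryError(f"units.length: unsupported unit {lu!r}")
    if au not in _AREA_TO_CM2:
        raise GeometryError(f"units.area: unsupported unit {au!r}")
    lscale, ascale = _LENGTH_TO_MM[lu], _AREA_TO_CM2[au]

    joints = data.get("joints")
    if not isinstance(joints, dict) or "left" not in joints or "right" not in joints:
        raise GeometryError("joints: must be an object with 'left' and 'right'")
    joint_left = _point(joints["left"], "joints.left", lscale)
    joint_right = _point(joints["right"], "joints.right", lscale)

    muscles = []
    for i, raw in enumerate(data.get("muscles", [])):
        where = f"muscles[{i}]"
        for key in ("name", "group", "side", "origin", "insertion", "acsa"):
            if key not in raw:
                raise GeometryError(f"{where}.{key}: required field missing")
        try:
            acsa = float(raw["acsa"]) * ascale
        except (TypeError, ValueError):
            raise GeometryError(f"{where}.acsa: must be numeric, got {raw['acsa']!r}") from None
        muscles.append(
            MuscleBundle(
                name=str(raw["name"]),
                group=str(raw["group"]),
                side=str(raw["side"]),
                origin=_point(raw["origin"], f"{where}.origin", lscale),
                insertion=_point(raw["insertion"], f"{where}.insertion", lscale),
                acsa=acsa,
                volume=None if raw.get("volume") is None else float(raw["volume"]),
                fiber_length=None
                if raw.get("fiber_length") is None
                else float(raw["fiber_length"]),
            )
        )

    bite_points = []
    for i, raw in enumerate(data.get("bite_points", [])):
        where = f"bite_points[{i}]"
        for key in ("label", "position"):
            if key not in raw:
                raise GeometryError(f"{where}.{key}: required field missing")
        bite_points.append(
            BitePoint(str(raw["label"]), _point(raw["position"], f"{where}.position", lscale))
        )

    model = JawModel(
        joint_left=joint_left,
        joint_right=joint_right,
        muscles=tuple(muscles),
        bite_points=tuple(bite_points),
        gape_reference_deg=float(data.get("gape_reference_deg", 0.0)),
        extra={k: v for k, v in data.items() if k not in _KNOWN_KEYS},
    )
    validate_jaw_model(model)
    return model


def write_jaw_model(model: JawModel, path) -> None:
    """Emit the geometry JSON schema (mm / cm²); unknown keys from ``extra``
    are preserved so load → write → load round-trips all fields."""
    data: dict = {
        "units": {"length": "mm", "area": "cm2"},
        "joints": {
            "left": list(model.joint_left.to_array()),
            "right": list(model.joint_right.to_array()),
        },
        "gape_reference_deg": model.gape_reference_deg,
        "muscles": [],
        "bite_points": [],
    }
    for m in model.muscles:
        raw = {
            "name": m.name,
            "group": m.group,
            "side": m.side,
            "origin": list(m.origin.to_array()),
            "insertion": list(m.insertion.to_array()),
            "acsa": m.acsa,
        }
        if m.volume is not None:
            raw["volume"] = m.volume
        if m.fiber_length is not None:
            raw["fiber_length"] = m.fiber_length
        data["muscles"].append(raw)
    for bp in model.bite_points:
        data["bite_points"].append({"label": bp.label, "position": list(bp.position.to_array())})
    data.update(model.extra)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


# ---------------------------------------------------------------------------
# hinge axis, mirroring, rotation

def joint_axis(model: JawModel) -> tuple[Point3, np.ndarray]:
    """Hinge center (midpoint of the two joints) and unit axis direction
    (right joint toward left joint)."""
    jl, jr = model.joint_left.to_array(), model.joint_right.to_array()
    d = jl - jr
    n = np.linalg.norm(d)
    if n < _AXIS_TOL:
        raise GeometryError("degenerate joint axis: left and right joints coincide")
    return Point3.from_array((jl + jr) / 2.0), d / n


def mirror_unilateral(model: JawModel) -> JawModel:
    """Duplicate every bundle across the sagittal plane through the hinge
    midpoint (y → 2·y_mid − y), flipping sides. Requires a one-sided model."""
    sides = model.sides_present()
    if len(sides) != 1:
        raise GeometryError(
            "model is already bilateral; skip mirroring (mirror_unilateral expects "
            "muscles of a single side)"
        )
    center, _ = joint_axis(model)
    yc = center.y

    def reflect(p: Point3) -> Point3:
        return Point3(p.x, 2.0 * yc - p.y, p.z)

    other = {"left": "right", "right": "left"}
    mirrored = tuple(
        dataclasses.replace(
            m, side=other[m.side], origin=reflect(m.origin), insertion=reflect(m.insertion)
        )
        for m in model.muscles
    )
    return dataclasses.replace(model, muscles=model.muscles + mirrored)


def rotate_about_axis(p: Point3, center: Point3, axis: np.ndarray, angle_deg: float) -> Point3:
    """Rodrigues rotation of ``p`` about the line (center, axis), right-hand
    rule about +axis. ``axis`` must be unit length."""
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > _UNIT_TOL:
        raise GeometryError(f"axis must be unit length, |axis| = {np.linalg.norm(axis):g}")
    ang = math.radians(angle_deg)
    r = p.to_array() - center.to_array()
    rot = (
        r * math.cos(ang)
        + np.cross(axis, r) * math.sin(ang)
        + axis * np.dot(axis, r) * (1.0 - math.cos(ang))
    )
    return Point3.from_array(center.to_array() + rot)


def opening_sense(model: JawModel) -> float:
    """Sign s such that rotating the mandible by +s about the hinge axis
    moves the jaw tip ventrally (−z), i.e. opens the jaw.

    Computed from geometry rather than hard-coded: the reference point is the
    ``jaw_tip`` bite point if present, otherwise the anterior-most bite point.
    """
    center, axis = joint_axis(model)
    try:
        ref = model.bite_point("jaw_tip").position
    except GeometryError:
        ref = max(model.bite_points, key=lambda bp: bp.position.x).position
    v = np.cross(axis, ref.to_array() - center.to_array())  # velocity under +rotation
    if abs(v[2]) < _AXIS_TOL:
        raise GeometryError(
            "cannot determine opening sense: reference bite point moves purely "
            "horizontally under hinge rotation"
        )
    return 1.0 if v[2] < 0 else -1.0


def open_jaw(model: JawModel, gape_deg: float) -> JawModel:
    """Pose the model at ``gape_deg`` by rigidly rotating all mandibular
    points (muscle insertions, bite points) about the hinge axis; cranial
    points (origins, joints) are fixed. The returned model's
    ``gape_reference_deg`` equals ``gape_deg``, making the operation a group
    action on poses."""
    if not (0 <= gape_deg < 90):
        raise GeometryError(f"gape must lie in [0, 90) degrees, got {gape_deg}")
    delta = gape_deg - model.gape_reference_deg
    if delta == 0:
        return model
    center, axis = joint_axis(model)
    angle = opening_sense(model) * delta

    muscles = tuple(
        dataclasses.replace(m, insertion=rotate_about_axis(m.insertion, center, axis, angle))
        for m in model.muscles
    )
    bite_points = tuple(
        BitePoint(bp.label, rotate_about_axis(bp.position, center, axis, angle))
        for bp in model.bite_points
    )
    return dataclasses.replace(
        model, muscles=muscles, bite_points=bite_points, gape_reference_deg=float(gape_deg)
    )
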