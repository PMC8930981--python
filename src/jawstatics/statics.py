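"""Static bite-force solver.

The mandible is a rigid body hinged at the quadrate-articular axis. With all
adductors maximally active, moment equilibrium about the hinge axis fixes the
magnitude of the food reaction force at a chosen bite point and reaction
orientation; full force balance then yields the joint reaction force.

Sign conventions are handled algebraically, not by a hard-coded closing
direction: the solved magnitude is ``-M_muscle / m_u`` where ``M_muscle`` is
the summed axial moment of the muscle forces and ``m_u`` the axial moment of a
unit reaction force at the bite point. A negative solution means the chosen
reaction orientation would require the food to pull the jaw shut; it is
clamped to zero and flagged rather than raised, because such orientations are
still informative inside a sweep.

The reaction orientation is measured in the plane perpendicular to the hinge
axis, from the vertical (dorsoventral) direction of the *closed-skull* frame:
the food sets the reaction direction, so it does not rotate with gape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .geometry import (
    BITE_POINT_LABELS,
    GeometryError,
    JawModel,
    Point3,
    joint_axis,
    open_jaw,
)
from .muscles import DEFAULT_MUSCLE_STRESS, muscle_force

__all__ = [
    "StaticsError",
    "ReactionOrientation",
    "BiteSolution",
    "SimulationConfig",
    "moment_about_axis",
    "reaction_direction",
    "solve_bite_force",
    "run_simulation",
    "percent_of_max",
    "round_half_up",
]

_UNIT_TOL = 1e-8
#: Minimum out-lever (mm) below which an orientation is unsolvable: the
#: reaction line passes through the hinge axis.
MIN_MOMENT_ARM = 1e-9


class StaticsError(ValueError):
    """Unsolvable equilibrium configuration."""


@dataclass(frozen=True)
class ReactionOrientation:
    """Direction of the food reaction force, as a rotation (degrees) about
    the hinge axis away from the closed-skull vertical; 0 = vertical bite."""

    angle_deg: float = 0.0

    def __post_init__(self):
        if not (-90 < self.angle_deg < 90):
            raise StaticsError(
                f"reaction orientation must lie in (-90, 90) degrees, got {self.angle_deg}"
            )


@dataclass(frozen=True)
class BiteSolution:
    """One solved static equilibrium: bite-force magnitude plus the joint
    reaction force balancing muscles and food reaction.

    ``joint_force_orientation_deg`` is the joint force's angle from vertical
    in the sagittal (x-z) projection; ``clamped`` marks orientations the jaw
    cannot resist (solved magnitude was negative, reported as 0).
    """

    bite_point_label: str
    gape_deg: float
    orientation: ReactionOrientation
    bite_force: float
    joint_force: np.ndarray
    joint_force_magnitude: float
    joint_force_orientation_deg: float
    clamped: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Sweep layout: gape angles, bite points, reaction-orientation range and
    muscle stress. Defaults follow the standard protocol (gapes 10/30/60,
    all four tooth-row points, orientations -30..+30 in 5 degree steps,
    stress 30 N/cm²)."""

    gapes_deg: tuple[float, ...] = (10.0, 30.0, 60.0)
    bite_point_labels: tuple[str, ...] | None = None  # None = all in the model
    orientation_min_deg: float = -30.0
    orientation_max_deg: float = 30.0
    orientation_step_deg: float = 5.0
    muscle_stress: float = DEFAULT_MUSCLE_STRESS

    def __post_init__(self):
        for g in self.gapes_deg:
            if not (0 <= g < 90):
                raise StaticsError(f"gape angles must lie in [0, 90), got {g}")
        if not (self.orientation_step_deg > 0):
            raise StaticsError("orientation step must be > 0")
        if self.orientation_max_deg < self.orientation_min_deg:
            raise StaticsError("orientation_max_deg < orientation_min_deg")
        if not (self.muscle_stress > 0):
            raise StaticsError("muscle stress must be > 0")

    def orientations(self) -> np.ndarray:
        n = int(round((self.orientation_max_deg - self.orientation_min_deg)
                      / self.orientation_step_deg))
        return self.orientation_min_deg + self.orientation_step_deg * np.arange(n + 1)


def moment_about_axis(
    force: np.ndarray, application_point: Point3, center: Point3, axis: np.ndarray
) -> float:
    """Axial moment ((r × F) · axis) of a force about the hinge line, N·mm."""
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > _UNIT_TOL:
        raise StaticsError(f"axis must be unit length, |axis| = {np.linalg.norm(axis):g}")
    r = application_point.to_array() - center.to_array()
    return float(np.dot(np.cross(r, np.asarray(force, dtype=float)), axis))


def reaction_direction(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit direction of the food reaction on the mandible: the ventral
    direction projected perpendicular to the hinge axis, rotated by
    ``angle_deg`` about the axis."""
    axis = np.asarray(axis, dtype=float)
    down = np.array([0.0, 0.0, -1.0])
    d = down - np.dot(down, axis) * axis
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise StaticsError("hinge axis is vertical; no well-defined vertical bite direction")
    d /= n
    ang = math.radians(angle_deg)
    return d * math.cos(ang) + np.cross(axis, d) * math.sin(ang)


def solve_bite_force(
    model: JawModel,
    bite_point_label: str,
    gape_deg: float,
    orientation: ReactionOrientation | float = 0.0,
    stress: float = DEFAULT_MUSCLE_STRESS,
) -> BiteSolution:
    """Solve the static force equilibrium at one (bite point, gape, reaction
    orientation) condition.

    Steps: pose the model at the gape; form each bundle's force (acsa ×
    stress along insertion → origin); sum axial moments about the hinge; find
    the reaction magnitude that balances them; recover the joint reaction
    from full force balance. The reported ``bite_force`` is the magnitude the
    jaw exerts on the food (equal and opposite to the reaction on the jaw).
    """
    if not isinstance(orientation, ReactionOrientation):
        orientation = ReactionOrientation(float(orientation))
    if len(model.sides_present()) == 1:
        warnings.warn(
            "model has muscles on one side only; solving anyway — consider "
            "mirror_unilateral() for a bilateral model",
            stacklevel=2,
        )

    pose = open_jaw(model, gape_deg)
    center, axis = joint_axis(pose)
    bp = pose.bite_point(bite_point_label)

    forces = [muscle_force(m, stress) for m in pose.muscles]
    total_muscle_moment = sum(
        moment_about_axis(f.vector(), f.application_point, center, axis) for f in forces
    )
    u = reaction_direction(axis, orientation.angle_deg)
    m_u = moment_about_axis(u, bp.position, center, axis)
    if abs(m_u) < MIN_MOMENT_ARM:
        raise StaticsError(
            f"reaction orientation {orientation.angle_deg} deg at {bite_point_label!r} "
            "has zero moment arm about the hinge (line of action through the joint)"
        )

    magnitude = -total_muscle_moment / m_u
    clamped = magnitude < 0
    if clamped:
        magnitude = 0.0

    sum_muscle = sum((f.vector() for f in forces), start=np.zeros(3))
    joint = -(sum_muscle + magnitude * u)
    return BiteSolution(
        bite_point_label=bite_point_label,
        gape_deg=float(gape_deg),
        orientation=orientation,
        bite_force=magnitude,
        joint_force=joint,
        joint_force_magnitude=float(np.linalg.norm(joint)),
        joint_force_orientation_deg=math.degrees(math.atan2(joint[0], joint[2])),
        clamped=clamped,
    )


_COLUMNS = [
    "bite_point",
    "gape_deg",
    "orientation_deg",
    "bite_force_N",
    "joint_force_N",
    "joint_angle_deg",
    "status",
    "is_max",
]


def run_simulation(model: JawModel, config: SimulationConfig | None = None) -> pd.DataFrame:
    """Sweep gapes × bite points × reaction orientations; one row per
    condition. Solver failures are recorded in ``status`` and the run
    continues. The per-(gape, bite point) maximum over orientations is
    flagged in ``is_max``."""
    config = config or SimulationConfig()
    labels = config.bite_point_labels
    if labels is None:
        labels = tuple(bp.label for bp in model.bite_points)
    else:
        for lb in labels:
            model.bite_point(lb)  # raise early on unknown labels

    if len(model.sides_present()) == 1:
        warnings.warn("simulating a one-sided (unilateral) muscle set", stacklevel=2)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-solve unilateral warning already issued once
        for gape in config.gapes_deg:
            for label in labels:
                for theta in config.orientations():
                    try:
                        sol = solve_bite_force(
                            model, label, gape, float(theta), config.muscle_stress
                        )
                        rows.append(
                            {
                                "bite_point": label,
                                "gape_deg": float(gape),
                                "orientation_deg": float(theta),
                                "bite_force_N": sol.bite_force,
                                "joint_force_N": sol.joint_force_magnitude,
                                "joint_angle_deg": sol.joint_force_orientation_deg,
                                "status": "clamped" if sol.clamped else "ok",
                                "is_max": False,
                            }
                        )
                    except (StaticsError, GeometryError) as exc:
                        rows.append(
                            {
                                "bite_point": label,
                                "gape_deg": float(gape),
                                "orientation_deg": float(theta),
                                "bite_force_N": np.nan,
                                "joint_force_N": np.nan,
                                "joint_angle_deg": np.nan,
                                "status": f"error: {exc}",
                                "is_max": False,
                            }
                        )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    for (_, _), grp in df.groupby(["gape_deg", "bite_point"]):
        solved = grp["bite_force_N"].dropna()
        if len(solved):
            df.loc[solved.idxmax(), "is_max"] = True
    return df


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero upward."""
    return int(math.floor(x + 0.5))


def percent_of_max(results: pd.DataFrame) -> pd.DataFrame:
    """Annotate every solved row with its bite force as an integer percent of
    the global maximum (round-half-up); the maximum row reads 100."""
    if len(results) == 0:
        raise StaticsError("percent_of_max: empty results table")
    solved = results["bite_force_N"].dropna()
    if len(solved) == 0:
        raise StaticsError("percent_of_max: no solved rows")
    max_force = solved.max()
    if max_force <= 0:
        raise StaticsError("percent_of_max: maximum bite force is not positive")
    out = results.copy()
    out["pct_of_max"] = pd.array(
        [
            round_half_up(100.0 * f / max_force) if np.isfinite(f) else pd.NA
            for f in out["bite_force_N"]
        ],
        dtype="Int64",
    )
    return out
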