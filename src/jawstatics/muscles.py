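"""Muscle force generation from architecture.

A maximally active bundle produces ``acsa × muscle_stress`` newtons along the
straight line from insertion to origin (no pennation correction, no
force-length or force-velocity scaling). The default muscle stress is the
conventional squamate estimate of 30 N/cm².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import MuscleBundle, Point3

__all__ = [
    "DEFAULT_MUSCLE_STRESS",
    "MuscleForce",
    "acsa_from_volume",
    "muscle_force",
    "attachment_centroid",
    "group_volume_fractions",
]

#: Maximal isometric force per unit cross-sectional area, N/cm².
DEFAULT_MUSCLE_STRESS = 30.0


@dataclass(frozen=True)
class MuscleForce:
    """Force of one maximally active bundle: ``magnitude`` N applied at the
    insertion, directed from insertion toward origin."""

    bundle_name: str
    application_point: Point3
    direction: np.ndarray
    magnitude: float

    def vector(self) -> np.ndarray:
        return self.magnitude * self.direction


def acsa_from_volume(volume: float, fiber_length: float) -> float:
    """Cross-sectional area (cm²) from muscle volume (cm³) and fiber length
    (cm), the standard volume/length reduction."""
    if not (volume > 0):
        raise ValueError(f"volume must be > 0, got {volume}")
    if not (fiber_length > 0):
        raise ValueError(f"fiber_length must be > 0, got {fiber_length}")
    return volume / fiber_length


def muscle_force(bundle: MuscleBundle, stress: float = DEFAULT_MUSCLE_STRESS) -> MuscleForce:
    """Force of a maximally active bundle at a given muscle stress (N/cm²)."""
    if not (stress > 0):
        raise ValueError(f"muscle stress must be > 0, got {stress}")
    d = bundle.origin.to_array() - bundle.insertion.to_array()
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError(f"bundle {bundle.name!r}: zero-length line of action")
    return MuscleForce(
        bundle_name=bundle.name,
        application_point=bundle.insertion,
        direction=d / n,
        magnitude=bundle.acsa * stress,
    )


def attachment_centroid(
    points: Sequence[Point3], weights: Iterable[float] | None = None
) -> Point3:
    """(Area-weighted) centroid of an attachment site, for bundles with broad
    origin or insertion areas digitized as multiple landmarks."""
    if len(points) == 0:
        raise ValueError("attachment_centroid requires at least one point")
    arr = np.array([p.to_array() for p in points])
    if weights is None:
        return Point3.from_array(arr.mean(axis=0))
    w = np.asarray(list(weights), dtype=float)
    if w.shape[0] != arr.shape[0]:
        raise ValueError("weights must match points in length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return Point3.from_array((arr * w[:, None]).sum(axis=0) / w.sum())


def group_volume_fractions(muscles: Sequence[MuscleBundle]) -> Mapping[str, float]:
    """Fraction of total adductor volume per muscle group.

    Every bundle must carry a volume; fractions sum to 1 and are invariant to
    rescaling all volumes.
    """
    if len(muscles) == 0:
        raise ValueError("no muscle bundles given")
    for m in muscles:
        if m.volume is None:
            raise ValueError(f"bundle {m.name!r} has no volume")
    totals: dict[str, float] = {}
    for m in muscles:
        totals[m.group] = totals.get(m.group, 0.0) + float(m.volume)
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total muscle volume must be positive")
    return {g: v / grand for g, v in totals.items()}
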