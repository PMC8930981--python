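"""Seeded generators for every input the pipeline consumes.

Three families:

* jaw geometries — a *planar* family whose bite forces have a scalar
  closed-form (all fibers parallel in the sagittal plane, levers known
  exactly, recomputable analytically at any gape and reaction orientation),
  and a *random* 3D family of anatomically plausible models for oracle
  testing;
* comparative in vivo datasets emulating the field protocol: species head
  widths log-spaced, a log10-linear bite-force-head-width relationship with
  species- and specimen-level deviations, and each animal's recorded force
  the maximum of five noisy trials;
* crab-exoskeleton hardness records, failure force linear in carapace width.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, stats

from .allometry import HardnessRecord, SpecimenRecord
from .geometry import (
    BITE_POINT_LABELS,
    BitePoint,
    JawModel,
    MuscleBundle,
    Point3,
    validate_jaw_model,
)
from .muscles import DEFAULT_MUSCLE_STRESS

__all__ = [
    "SyntheticJawParams",
    "SyntheticComparativeParams",
    "planar_bite_force",
    "make_planar_jaw",
    "make_random_jaw",
    "make_comparative_dataset",
    "make_hardness_dataset",
    "expected_max_trial_log10_shift",
]

_GROUP_CYCLE = ("external_adductor", "pseudotemporalis", "pterygoideus")


@dataclass(frozen=True)
class SyntheticJawParams:
    """Planar jaw family layout.

    In-levers are perpendicular distances (mm) from the hinge to each
    fiber's line of action at the closed pose; out-levers are the bite
    points' distances along the mandible, ordered anterior > posterior.
    ``fiber_tilt_deg`` tilts all fibers posteriorly from vertical so that
    origins sit at or behind the hinge, the configuration under which bite
    force declines with gape; ``origin_elevation`` is the dorsal height (mm)
    of every origin.
    """

    n_bundles_per_side: int = 3
    in_lever_range: tuple[float, float] = (5.0, 12.0)
    out_levers: Mapping[str, float] = field(
        default_factory=lambda: {
            "jaw_tip": 40.0,
            "anterior_caniniform": 32.0,
            "posterior_caniniform": 24.0,
            "posterior_most": 18.0,
        }
    )
    total_acsa: float = 4.0
    origin_elevation: float = 18.0
    fiber_tilt_deg: float = 45.0
    joint_half_width: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bundles_per_side < 1:
            raise ValueError("need at least one bundle per side")
        lo, hi = self.in_lever_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid in_lever_range {self.in_lever_range}")
        if not (self.total_acsa > 0 and self.origin_elevation > 0):
            raise ValueError("total_acsa and origin_elevation must be > 0")
        ordered = [lb for lb in BITE_POINT_LABELS if lb in self.out_levers]
        vals = [self.out_levers[lb] for lb in ordered]
        if any(v <= 0 for v in vals):
            raise ValueError("out-levers must be positive")
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise ValueError(
                "out-levers must decrease from jaw_tip to posterior_most "
                f"(anterior points are farther from the joint), got {dict(self.out_levers)}"
            )


@dataclass(frozen=True)
class SyntheticComparativeParams:
    """Generating conditions of the comparative in vivo dataset.

    ``slope``/``intercept`` define the true log10 bite-force-head-width
    line; ``species_sd``/``specimen_sd`` are log10-scale deviations shared by
    a species and private to a specimen; each animal's recorded force is the
    maximum of ``trials_per_individual`` trials with lognormal noise of
    coefficient of variation ``trial_cv`` around its true capacity.
    """

    n_species: int = 44
    n_specimens: int = 332
    slope: float = 2.0
    intercept: float = -1.0
    species_sd: float = 0.15
    specimen_sd: float = 0.10
    trials_per_individual: int = 5
    trial_cv: float = 0.10
    head_width_range: tuple[float, float] = (5.0, 55.0)
    head_width_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < self.n_species:
            raise ValueError("n_specimens must be >= n_species")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        for name in ("species_sd", "specimen_sd", "trial_cv", "head_width_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trials_per_individual < 1:
            raise ValueError("need at least one trial per individual")
        lo, hi = self.head_width_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid head_width_range {self.head_width_range}")


# ---------------------------------------------------------------------------
# planar closed form

def planar_bite_force(
    bundles: Sequence[tuple[float, float, float, float]],
    out_lever: float,
    gape_deg: float,
    orientation_deg: float = 0.0,
) -> float:
    """Scalar lever-law bite force for a sagittal-plane jaw, any gape and
    reaction orientation.

    Each bundle is ``(insertion_x, origin_x, origin_z, force_N)`` in the
    closed pose with the hinge at the origin of the x-z plane (x anterior,
    z dorsal; insertions on the tooth row at z=0). Opening by ``g`` moves an
    insertion ``(r, 0)`` to ``(r cos g, -r sin g)`` while origins stay fixed;
    the closing moment of a unit force along the fiber is then
    ``r (x_o sin g + z_o cos g) / L`` with ``L`` the fiber length at that
    pose. The food reaction stays vertical in the closed-skull frame rotated
    by the orientation angle, so its out-lever is ``R cos(g - theta)``. The
    bite force is the ratio of summed closing moments to that out-lever;
    non-resisting configurations return 0.

    This is an independent analytic path (pure 2D trigonometry) against
    which the 3D vector solver is checked.
    """
    g = math.radians(gape_deg)
    theta = math.radians(orientation_deg)
    out_arm = out_lever * math.cos(g - theta)
    if abs(out_arm) < 1e-12:
        raise ValueError("reaction line passes through the hinge (zero out-lever)")
    closing = 0.0
    for r, xo, zo, force in bundles:
        px, pz = r * math.cos(g), -r * math.sin(g)
        dx, dz = xo - px, zo - pz
        length = math.hypot(dx, dz)
        if length < 1e-12:
            raise ValueError("degenerate fiber (origin at rotated insertion)")
        closing += force * r * (xo * math.sin(g) + zo * math.cos(g)) / length
    bite = closing / out_arm
    return bite if bite > 0 else 0.0


def make_planar_jaw(
    params: SyntheticJawParams | None = None,
    stress: float = DEFAULT_MUSCLE_STRESS,
    expected_gapes: Sequence[float] = (0.0, 10.0, 30.0, 60.0),
) -> tuple[JawModel, dict[tuple[str, float], float]]:
    """Build a bilateral planar jaw with exactly known levers and return it
    with the closed-form expected bite force per (bite point, gape) at the
    vertical (0 deg) reaction orientation."""
    params = params or SyntheticJawParams()
    rng = np.random.default_rng(params.seed)
    tilt = math.radians(params.fiber_tilt_deg)
    h = params.origin_elevation

    in_levers = rng.uniform(*params.in_lever_range, params.n_bundles_per_side)
    weights = rng.uniform(0.5, 1.5, params.n_bundles_per_side)
    acsas = weights / weights.sum() * (params.total_acsa / 2.0)  # per side

    yw = params.joint_half_width
    muscles: list[MuscleBundle] = []
    planar: list[tuple[float, float, float, float]] = []
    for i, (a, acsa) in enumerate(zip(in_levers, acsas)):
        # perpendicular lever a at the closed pose for a fiber tilted
        # posteriorly by `tilt` from vertical: insertion_x = a / cos(tilt)
        xi = a / math.cos(tilt)
        xo = xi - h * math.tan(tilt)
        group = _GROUP_CYCLE[i % len(_GROUP_CYCLE)]
        for side, ys in (("left", yw - 1.0), ("right", -(yw - 1.0))):
            muscles.append(
                MuscleBundle(
                    name=f"{group}_{i}_{side}",
                    group=group,
                    side=side,
                    origin=Point3(xo, ys, h),
                    insertion=Point3(xi, ys, 0.0),
                    acsa=float(acsa),
                )
            )
        planar.append((xi, xo, h, float(2.0 * acsa * stress)))  # both sides

    bite_points = tuple(
        BitePoint(lb, Point3(params.out_levers[lb], 0.0, 0.0))
        for lb in BITE_POINT_LABELS
        if lb in params.out_levers
    )
    model = JawModel(
        joint_left=Point3(0.0, yw, 0.0),
        joint_right=Point3(0.0, -yw, 0.0),
        muscles=tuple(muscles),
        bite_points=bite_points,
    )
    validate_jaw_model(model)

    expected = {
        (bp.label, float(g)): planar_bite_force(planar, params.out_levers[bp.label], g)
        for bp in bite_points
        for g in expected_gapes
    }
    return model, expected


def make_random_jaw(
    params: SyntheticJawParams | None = None, seed: int | None = None
) -> JawModel:
    """A random anatomically plausible bilateral 3D jaw: insertions on the
    mandible between joint and tip, origins dorsal and posterior to them,
    tooth-row bite points in the required anterior-posterior order.
    Deterministic for a given seed."""
    params = params or SyntheticJawParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    jaw_length = rng.uniform(30.0, 45.0)
    half_width = rng.uniform(3.5, 5.0)
    muscles: list[MuscleBundle] = []
    for i in range(params.n_bundles_per_side):
        ins_x = rng.uniform(0.15, 0.5) * jaw_length
        ins_z = rng.uniform(-1.0, 1.0)
        ori_x = ins_x - rng.uniform(1.0, 8.0)
        ori_z = ins_z + rng.uniform(8.0, 20.0)
        acsa = rng.uniform(0.2, 1.5)
        group = _GROUP_CYCLE[i % len(_GROUP_CYCLE)]
        ins_y = half_width - rng.uniform(0.0, 1.5)
        ori_y = half_width + rng.uniform(-1.0, 2.0)
        for side, sign in (("left", 1.0), ("right", -1.0)):
            muscles.append(
                MuscleBundle(
                    name=f"{group}_{i}_{side}",
                    group=group,
                    side=side,
                    origin=Point3(ori_x, sign * ori_y, ori_z),
                    insertion=Point3(ins_x, sign * ins_y, ins_z),
                    acsa=acsa,
                )
            )

    fracs = np.sort(rng.uniform(0.4, 0.95, 3))[::-1]  # posterior three points
    dists = [jaw_length, *(jaw_length * fracs)]
    bite_points = tuple(
        BitePoint(lb, Point3(d, 0.0, float(rng.uniform(0.0, 1.5))))
        for lb, d in zip(BITE_POINT_LABELS, dists)
    )
    model = JawModel(
        joint_left=Point3(0.0, half_width, 0.0),
        joint_right=Point3(0.0, -half_width, 0.0),
        muscles=tuple(muscles),
        bite_points=bite_points,
    )
    validate_jaw_model(model)
    return model


# ---------------------------------------------------------------------------
# comparative in vivo dataset

def _sigma_ln(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def expected_max_trial_log10_shift(trial_cv: float, n_trials: int = 5) -> float:
    """Expected log10 offset of a recorded (max-of-n-trials) force above the
    true capacity, for lognormal trial noise of the given coefficient of
    variation: sigma_ln x E[max of n standard normals], converted to log10.

    The order-statistic mean is computed by exact quadrature, making this an
    analytic companion to the generator rather than a simulation.
    """
    if trial_cv == 0 or n_trials == 1:
        return 0.0
    ez, _ = integrate.quad(
        lambda z: z * n_trials * stats.norm.pdf(z) * stats.norm.cdf(z) ** (n_trials - 1),
        -np.inf,
        np.inf,
    )
    return _sigma_ln(trial_cv) * ez * math.log10(math.e)


def make_comparative_dataset(
    params: SyntheticComparativeParams | None = None,
) -> list[SpecimenRecord]:
    """Simulate the comparative in vivo protocol.

    Species head widths are log-spaced across ``head_width_range``; specimen
    head widths jitter around their species value. True capacity follows the
    generating log10 line plus species and specimen deviations; the recorded
    force is the maximum of ``trials_per_individual`` lognormal-noise trials,
    as when an animal bites a transducer repeatedly and the session maximum
    is kept.
    """
    params = params or SyntheticComparativeParams()
    rng = np.random.default_rng(params.seed)

    lo, hi = params.head_width_range
    species_hw = np.logspace(math.log10(lo), math.log10(hi), params.n_species)
    species_eff = rng.normal(0.0, params.species_sd, params.n_species)

    base, extra = divmod(params.n_specimens, params.n_species)
    counts = [base + (1 if i < extra else 0) for i in range(params.n_species)]

    sigma_t = _sigma_ln(params.trial_cv)
    records: list[SpecimenRecord] = []
    for s in range(params.n_species):
        name = f"sp{s + 1:02d}"
        for _ in range(counts[s]):
            hw = species_hw[s] * 10.0 ** rng.normal(0.0, params.head_width_jitter_sd)
            log_capacity = (
                params.intercept
                + params.slope * math.log10(hw)
                + species_eff[s]
                + rng.normal(0.0, params.specimen_sd)
            )
            capacity = 10.0**log_capacity
            trials = capacity * np.exp(
                rng.normal(0.0, sigma_t, params.trials_per_individual)
            )
            records.append(
                SpecimenRecord(
                    species=name,
                    head_width=float(hw),
                    bite_force=float(trials.max()),
                    svl=float(hw * rng.uniform(5.5, 7.5)),
                )
            )
    return records


# ---------------------------------------------------------------------------
# crab hardness

def make_hardness_dataset(
    slope: float = 42.5,
    intercept: float = 0.0,
    sd: float = 8.0,
    n: int = 30,
    seed: int = 0,
    width_range: tuple[float, float] = (2.0, 6.0),
) -> list[HardnessRecord]:
    """Crab-exoskeleton failure forces linear in carapace width (cm) with
    Gaussian noise (floored at 0.1 N). Widths are uniform over the adult
    size range; mass scales with the cube of width as for an isometric
    crab."""
    if n < 1:
        raise ValueError("need n >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    widths = rng.uniform(*width_range, n)
    records = []
    for w in widths:
        force = max(intercept + slope * w + rng.normal(0.0, sd), 0.1)
        mass = 0.7 * w**3 * math.exp(rng.normal(0.0, 0.1))
        records.append(HardnessRecord(float(w), float(mass), float(force)))
    return records
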