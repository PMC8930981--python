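"""Comparative scaling: bite-force allometry across skinks and prey
(crab exoskeleton) hardness.

In vivo maximal bite forces scale with head width approximately as a power
law, so the cross-species relationship is fitted by ordinary least squares on
log10-log10 axes. A model-estimated species with no in vivo measurement is
placed on that line via its signed log10 residual. Exoskeleton failure force
is fitted on untransformed axes, hardness being close to linear in carapace
size over the relevant range.

Specimens are treated as exchangeable points by default, matching a
specimen-level scatter plot; a per-species-means fit is available and is the
appropriate choice for inference, because specimens of one species share that
species' deviation from the allometric line and a specimen-level fit
overstates the effective sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpecimenRecord",
    "AllometricFit",
    "HardnessRecord",
    "LinearFit",
    "HardnessMargin",
    "fit_loglog",
    "residual_position",
    "fit_hardness_vs_size",
    "exceeds_hardness",
    "read_specimen_csv",
    "write_specimen_csv",
    "read_hardness_csv",
    "write_hardness_csv",
]


@dataclass(frozen=True)
class SpecimenRecord:
    """One animal: species, head width (mm) and maximal in vivo bite force
    (N); snout-vent length (mm) optional."""

    species: str
    head_width: float
    bite_force: float
    svl: float | None = None

    def __post_init__(self):
        if not (self.head_width > 0):
            raise ValueError(f"head_width must be > 0, got {self.head_width}")
        if not (self.bite_force > 0):
            raise ValueError(f"bite_force must be > 0, got {self.bite_force}")


@dataclass(frozen=True)
class AllometricFit:
    """OLS line of log10(bite force, N) on log10(head width, mm)."""

    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n: int
    slope_se: float
    intercept_se: float
    per_species: bool = False

    def predict_log10(self, head_width: float) -> float:
        return self.intercept + self.slope * math.log10(head_width)

    def predict(self, head_width: float) -> float:
        """Predicted bite force in newtons."""
        return 10.0 ** self.predict_log10(head_width)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se


@dataclass(frozen=True)
class HardnessRecord:
    """One crushed specimen: carapace width (cm), mass (g) and the force at
    which the exoskeleton's external surface failed (N)."""

    carapace_width: float
    mass: float
    failure_force: float

    def __post_init__(self):
        for name in ("carapace_width", "mass", "failure_force"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class LinearFit:
    """OLS line of failure force (N) on carapace width (cm), untransformed."""

    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n: int
    slope_se: float

    def predict(self, carapace_width: float) -> float:
        return self.intercept + self.slope * carapace_width


@dataclass(frozen=True)
class HardnessMargin:
    """Predator-vs-prey comparison: does the bite force reach the predicted
    failure force of the prey's exoskeleton?"""

    bite_force: float
    hardness: float
    difference: float
    ratio: float
    exceeds: bool
    at_boundary: bool


def fit_loglog(
    records: Sequence[SpecimenRecord], per_species: bool = False
) -> AllometricFit:
    """Fit the bite-force-head-width allometry by OLS on log10 axes.

    With ``per_species=True`` the regression runs on species means of the
    log10 values (one point per species), the pseudoreplication-safe variant.
    """
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    x = np.log10([r.head_width for r in records])
    y = np.log10([r.bite_force for r in records])
    if per_species:
        df = pd.DataFrame({"species": [r.species for r in records], "x": x, "y": y})
        means = df.groupby("species", sort=True).mean()
        x, y = means["x"].to_numpy(), means["y"].to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 species for a per-species fit")
    if np.ptp(x) < 1e-12 or len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct head widths with non-zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    n = len(x)
    return AllometricFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / (n - 2))),
        n=n,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        per_species=per_species,
    )


def residual_position(fit: AllometricFit, head_width: float, bite_force: float) -> float:
    """Signed log10 residual of an (head width, bite force) point relative to
    the fitted allometric line; positive = above the line."""
    if not (head_width > 0):
        raise ValueError(f"head_width must be > 0, got {head_width}")
    if not (bite_force > 0):
        raise ValueError(f"bite_force must be > 0, got {bite_force}")
    return math.log10(bite_force) - fit.predict_log10(head_width)


def fit_hardness_vs_size(records: Sequence[HardnessRecord]) -> LinearFit:
    """Fit exoskeleton failure force against carapace width (untransformed
    OLS)."""
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    x = np.array([r.carapace_width for r in records])
    y = np.array([r.failure_force for r in records])
    if np.ptp(x) < 1e-12:
        raise ValueError("carapace widths have zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / (len(x) - 2))),
        n=len(x),
        slope_se=float(res.stderr),
    )


def exceeds_hardness(bite_force: float, predicted_hardness: float) -> HardnessMargin:
    """Compare a bite force against a predicted prey failure force."""
    if not (bite_force > 0):
        raise ValueError(f"bite_force must be > 0, got {bite_force}")
    if not (predicted_hardness > 0):
        raise ValueError(f"predicted_hardness must be > 0, got {predicted_hardness}")
    diff = bite_force - predicted_hardness
    return HardnessMargin(
        bite_force=bite_force,
        hardness=predicted_hardness,
        difference=diff,
        ratio=bite_force / predicted_hardness,
        exceeds=bite_force >= predicted_hardness,
        at_boundary=math.isclose(bite_force, predicted_hardness, rel_tol=1e-12),
    )


# ---------------------------------------------------------------------------
# CSV interchange

def read_specimen_csv(path) -> list[SpecimenRecord]:
    """Columns: species, head_width_mm, bite_force_N, optional svl_mm."""
    df = pd.read_csv(path)
    for col in ("species", "head_width_mm", "bite_force_N"):
        if col not in df.columns:
            raise ValueError(f"comparative CSV missing column {col!r}")
    has_svl = "svl_mm" in df.columns
    return [
        SpecimenRecord(
            species=str(row.species),
            head_width=float(row.head_width_mm),
            bite_force=float(row.bite_force_N),
            svl=float(row.svl_mm) if has_svl and pd.notna(row.svl_mm) else None,
        )
        for row in df.itertuples()
    ]


def write_specimen_csv(records: Sequence[SpecimenRecord], path) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "head_width_mm": [r.head_width for r in records],
            "bite_force_N": [r.bite_force for r in records],
            "svl_mm": [r.svl for r in records],
        }
    ).to_csv(Path(path), index=False)


def read_hardness_csv(path) -> list[HardnessRecord]:
    """Columns: carapace_width_cm, mass_g, failure_force_N."""
    df = pd.read_csv(path)
    for col in ("carapace_width_cm", "mass_g", "failure_force_N"):
        if col not in df.columns:
            raise ValueError(f"hardness CSV missing column {col!r}")
    return [
        HardnessRecord(
            carapace_width=float(row.carapace_width_cm),
            mass=float(row.mass_g),
            failure_force=float(row.failure_force_N),
        )
        for row in df.itertuples()
    ]


def write_hardness_csv(records: Sequence[HardnessRecord], path) -> None:
    pd.DataFrame(
        {
            "carapace_width_cm": [r.carapace_width for r in records],
            "mass_g": [r.mass for r in records],
            "failure_force_N": [r.failure_force for r in records],
        }
    ).to_csv(Path(path), index=False)
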