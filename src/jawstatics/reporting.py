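"""Paper-style result summaries and the combined comparative report.

The combined report places a model-estimated species on the in vivo
allometric line and compares its bite force with predicted prey hardness.
Placement always uses the jaw-tip force at 30 degrees gape by default,
because that is how in vivo forces are measured (animals bite a transducer
at the tip of the jaw at roughly 30 degrees of gape); comparing any other
condition against the in vivo line would mix protocols.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
import pandas as pd

from .allometry import AllometricFit, LinearFit, exceeds_hardness, residual_position
from .statics import percent_of_max

__all__ = [
    "IN_VIVO_BITE_POINT",
    "IN_VIVO_GAPE_DEG",
    "summarize_results",
    "condition_max_force",
    "placement_verdict",
    "build_report",
]

#: The in vivo measurement condition: transducer at the tip of the jaw,
#: gape standardised near 30 degrees.
IN_VIVO_BITE_POINT = "jaw_tip"
IN_VIVO_GAPE_DEG = 30.0


def summarize_results(results: pd.DataFrame) -> dict[str, Any]:
    """Global maximum plus per-(gape, bite point) maxima with their percent
    of the global maximum."""
    pct = percent_of_max(results)
    solved = pct.dropna(subset=["bite_force_N"])
    best = solved.loc[solved["bite_force_N"].idxmax()]
    conditions = []
    for (gape, label), grp in solved.groupby(["gape_deg", "bite_point"]):
        row = grp.loc[grp["bite_force_N"].idxmax()]
        conditions.append(
            {
                "bite_point": label,
                "gape_deg": float(gape),
                "max_bite_force_N": float(row["bite_force_N"]),
                "orientation_deg": float(row["orientation_deg"]),
                "pct_of_max": int(row["pct_of_max"]),
            }
        )
    conditions.sort(key=lambda c: (c["gape_deg"], -c["max_bite_force_N"]))
    return {
        "max_bite_force_N": float(best["bite_force_N"]),
        "max_condition": {
            "bite_point": str(best["bite_point"]),
            "gape_deg": float(best["gape_deg"]),
            "orientation_deg": float(best["orientation_deg"]),
        },
        "n_rows": int(len(results)),
        "n_solved": int(len(solved)),
        "conditions": conditions,
    }


def condition_max_force(
    results: pd.DataFrame, bite_point: str, gape_deg: float
) -> float:
    """Maximum solved bite force over orientations at one (bite point, gape)
    condition."""
    sel = results[
        (results["bite_point"] == bite_point)
        & (np.isclose(results["gape_deg"], gape_deg))
    ]["bite_force_N"].dropna()
    if len(sel) == 0:
        raise ValueError(
            f"no solved rows for bite point {bite_point!r} at gape {gape_deg} deg"
        )
    return float(sel.max())


def placement_verdict(
    fit: AllometricFit, residual: float, band_sd: float = 1.0
) -> str:
    """Classify a residual against the point-level scatter of the fit:
    ``on`` within ``band_sd`` residual standard deviations, else ``above`` or
    ``below``."""
    band = band_sd * fit.residual_sd
    if residual > band:
        return "above"
    if residual < -band:
        return "below"
    return "on"


def build_report(
    results: pd.DataFrame,
    fit: AllometricFit,
    focal_head_width: float,
    focal_species: str = "focal",
    hardness_fit: LinearFit | None = None,
    prey_width_cm: float = 6.0,
    bite_point: str = IN_VIVO_BITE_POINT,
    gape_deg: float = IN_VIVO_GAPE_DEG,
) -> dict[str, Any]:
    """Combined comparative report.

    Uses the model's force at the in vivo-comparable condition (jaw tip, 30
    degrees by default) for placement on the allometric line, and the global
    maximum force for the prey-hardness verdict (prey hardness predicted at
    ``prey_width_cm``). The hardness section is omitted when no hardness fit
    is given.
    """
    placement_force = condition_max_force(results, bite_point, gape_deg)
    residual = residual_position(fit, focal_head_width, placement_force)
    report: dict[str, Any] = {
        "summary": summarize_results(results),
        "placement": {
            "species": focal_species,
            "bite_point": bite_point,
            "gape_deg": float(gape_deg),
            "head_width_mm": float(focal_head_width),
            "bite_force_N": placement_force,
            "predicted_in_vivo_N": fit.predict(focal_head_width),
            "log10_residual": residual,
            "verdict": placement_verdict(fit, residual),
            "fit": {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "residual_sd": fit.residual_sd,
                "n": fit.n,
                "per_species": fit.per_species,
            },
        },
    }
    if hardness_fit is not None:
        max_force = report["summary"]["max_bite_force_N"]
        hardness = hardness_fit.predict(prey_width_cm)
        margin = exceeds_hardness(max_force, hardness)
        report["hardness"] = {
            "prey_carapace_width_cm": float(prey_width_cm),
            "predicted_failure_force_N": hardness,
            "max_bite_force_N": max_force,
            "margin_N": margin.difference,
            "ratio": margin.ratio,
            "exceeds": margin.exceeds,
            "fit": {
                "slope_N_per_cm": hardness_fit.slope,
                "intercept_N": hardness_fit.intercept,
                "r2": hardness_fit.r2,
                "n": hardness_fit.n,
            },
        }
    return report
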