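"""Published empirical prediction equations for fat-free mass.

The catalogue holds the seven-model ladder developed on the 3.5-year
derivation cohort (weight W, standing height L, impedance index L²/R50, sex
S, ethnicity E), the two previously published preschool equations (Ejlerskov,
gram scale; Rush, kg scale), the scale-weight adjustment used to derive fat
mass, and the fat-mass subtraction itself.  All equations are exactly affine
in their covariates and are evaluated with the published coefficients.
"""

from __future__ import annotations

import warnings
from typing import Mapping

from .records import ChildRecord, ReferenceMeasurement  # noqa: F401  (module surface)

__all__ = [
    "EQUATION_CATALOGUE",
    "impedance_index",
    "ffm_nipper",
    "ffm_ejlerskov",
    "ffm_rush",
    "adjusted_weight",
    "fat_mass",
    "evaluate_equation",
]

# Development-cohort model ladder: coefficients on (W kg, L cm, L²/R50 cm²/Ω,
# S male indicator, E Asian indicator), FFM in kg.
EQUATION_CATALOGUE: Mapping[str, Mapping[str, float]] = {
    "w": {"intercept": 2.88, "w": 0.55},
    "w_l": {"intercept": -9.19, "w": 0.32, "l": 0.16},
    "w_l_s": {"intercept": -7.41, "w": 0.36, "l": 0.13, "s": 0.47},
    "w_idx": {"intercept": 1.49, "w": 0.26, "idx": 0.44},
    "w_idx_s": {"intercept": 1.55, "w": 0.30, "idx": 0.39, "s": 0.30},
    "nipper_anthro": {"intercept": -7.16, "w": 0.37, "l": 0.13, "s": 0.48, "e": 0.18},
    "nipper_final": {"intercept": 1.39, "w": 0.30, "idx": 0.39, "s": 0.30, "e": 0.28},
}

#: aliases: Table-row style ids for the two final models
_ALIASES = {"w_l_s_e": "nipper_anthro", "w_idx_s_e": "nipper_final"}


def impedance_index(height_cm: float, r50_ohm: float) -> float:
    """Impedance index L²/R50 (cm²/Ω), the standard BIA conductive-volume predictor."""
    if r50_ohm <= 0:
        raise ValueError(f"r50 must be positive, got {r50_ohm}")
    return height_cm**2 / r50_ohm


def evaluate_equation(coef: Mapping[str, float], child: ChildRecord) -> float:
    """Evaluate an affine FFM equation from the catalogue's coefficient layout."""
    ffm = coef["intercept"]
    ffm += coef.get("w", 0.0) * child.weight_scale_kg
    ffm += coef.get("l", 0.0) * child.height_cm
    if "idx" in coef:
        if child.r50_ohm is None:
            raise ValueError(
                f"child {child.child_id}: impedance-based equation requires r50_ohm"
            )
        ffm += coef["idx"] * impedance_index(child.height_cm, child.r50_ohm)
    ffm += coef.get("s", 0.0) * child.sex
    ffm += coef.get("e", 0.0) * child.ethnicity_asian
    return float(ffm)


def ffm_nipper(child: ChildRecord, model_id: str = "nipper_final") -> float:
    """FFM (kg) from one of the seven development-cohort models."""
    model_id = _ALIASES.get(model_id, model_id)
    if model_id not in EQUATION_CATALOGUE:
        raise KeyError(
            f"unknown model id {model_id!r}; choose from {sorted(EQUATION_CATALOGUE)}"
        )
    return evaluate_equation(EQUATION_CATALOGUE[model_id], child)


def ffm_ejlerskov(child: ChildRecord) -> float:
    """FFM (kg) from the Ejlerskov preschool equation (published in grams)."""
    if child.r50_ohm is None:
        raise ValueError("Ejlerskov equation requires r50_ohm")
    idx = impedance_index(child.height_cm, child.r50_ohm)
    ffm_g = (
        -2784.4
        + 327.2 * idx
        + 223.8 * child.weight_scale_kg
        + 76.8 * child.height_cm
        + 417.6 * child.sex
    )
    return ffm_g / 1000.0


def ffm_rush(child: ChildRecord) -> float:
    """FFM (kg) from the Rush toddler equation."""
    if child.r50_ohm is None:
        raise ValueError("Rush equation requires r50_ohm")
    idx = impedance_index(child.height_cm, child.r50_ohm)
    return (
        -2.490
        + 0.367 * idx
        + 0.188 * child.weight_scale_kg
        + 0.077 * child.height_cm
        + 0.273 * child.sex
    )


def adjusted_weight(weight_scale_kg: float) -> float:
    """Adjusted weight Wt_adj = 0.41 + 0.99 * scale weight (kg)."""
    return 0.41 + 0.99 * weight_scale_kg


def fat_mass(
    child: ChildRecord, ffm_pred_kg: float, weight_convention: str = "adjusted"
) -> float:
    """Fat mass as weight minus predicted FFM.

    ``weight_convention='adjusted'`` subtracts from the adjusted scale weight
    (the convention for the development-cohort and Ejlerskov equations);
    ``'scale'`` subtracts from raw scale weight (the Rush convention).
    Negative fat mass is returned with a warning.
    """
    if ffm_pred_kg < 0:
        raise ValueError("predicted FFM must be non-negative")
    if weight_convention == "adjusted":
        w = adjusted_weight(child.weight_scale_kg)
    elif weight_convention == "scale":
        w = child.weight_scale_kg
    else:
        raise ValueError(f"weight_convention must be adjusted|scale, got {weight_convention!r}")
    fm = w - ffm_pred_kg
    if fm < 0:
        warnings.warn(
            f"child {child.child_id}: predicted FFM exceeds {weight_convention} weight; "
            "negative fat mass",
            stacklevel=2,
        )
    return float(fm)
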