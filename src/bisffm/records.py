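"""Cohort record types: child covariates and reference DXA measurements."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = ["ChildRecord", "ReferenceMeasurement", "ethnicity_to_indicator"]

# Ethnicity collapse used for the Asian/non-Asian indicator; "Other" defaults
# to non-Asian.
_ASIAN_GROUPS = {"chinese", "south asian", "indian", "asian"}


def ethnicity_to_indicator(label: str) -> int:
    """Map a self-reported ethnicity label to the Asian (1) / non-Asian (0) indicator."""
    return int(label.strip().lower() in _ASIAN_GROUPS)


@dataclass
class ChildRecord:
    """One child's covariates at the 3.5-year visit.

    ``sex`` is the male indicator (M = 1, F = 0); ``ethnicity_asian`` is the
    Asian (1) / non-Asian (0) indicator.  ``r50_ohm`` is the Cole-derived
    resistance at 50 kHz and is optional: only impedance-based equations need
    it.  ``kb`` is an optional personalized body-geometry factor for the
    mixture-theory scheme that accepts one.

    Covariates outside the development cohort's plausible range (weight 5-40
    kg, height 70-130 cm) raise a warning, not an error: the prediction
    equations are documented as valid only near that range.
    """

    child_id: str
    sex: int
    ethnicity_asian: int
    age_days: float
    weight_scale_kg: float
    height_cm: float
    r50_ohm: Optional[float] = None
    kb: Optional[float] = None
    gestational_age_wk: Optional[float] = None
    birthweight_z: Optional[float] = None
    meal_category: Optional[int] = None
    void_category: Optional[int] = None

    def __post_init__(self):
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be the binary male indicator, got {self.sex!r}")
        if self.ethnicity_asian not in (0, 1):
            raise ValueError(
                f"ethnicity_asian must be binary, got {self.ethnicity_asian!r}"
            )
        if not 5 < self.weight_scale_kg < 40:
            warnings.warn(
                f"weight {self.weight_scale_kg} kg outside the 5-40 kg range the "
                "equations were developed for",
                stacklevel=2,
            )
        if not 70 < self.height_cm < 130:
            warnings.warn(
                f"height {self.height_cm} cm outside the 70-130 cm range the "
                "equations were developed for",
                stacklevel=2,
            )
        if self.r50_ohm is not None and self.r50_ohm <= 0:
            raise ValueError("r50_ohm must be positive when present")


@dataclass
class ReferenceMeasurement:
    """Whole-body reference composition from DXA for one child."""

    ffm_dxa_kg: float
    fm_dxa_kg: float
    fm_pct: Optional[float] = None
    lean_kg: Optional[float] = None
    bmc_g: Optional[float] = None
    weight_dxa_kg: Optional[float] = None

    def __post_init__(self):
        if self.weight_dxa_kg is not None:
            closure = self.ffm_dxa_kg + self.fm_dxa_kg
            if abs(closure - self.weight_dxa_kg) > 0.01 * self.weight_dxa_kg:
                warnings.warn(
                    f"FFM + FM = {closure:.3f} kg deviates from DXA weight "
                    f"{self.weight_dxa_kg:.3f} kg by more than 1%",
                    stacklevel=2,
                )
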