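"""Renal-function arithmetic: Cockcroft-Gault, CKD-EPI (2009), KDIGO bands.

Creatinine clearance enters the PK model in L/h; the single place the
mL/min -> L/h conversion factor lives is :data:`ML_MIN_TO_L_PER_H`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ML_MIN_TO_L_PER_H",
    "PatientCovariates",
    "RenalCategory",
    "cockcroft_gault",
    "ckd_epi",
    "kdigo_category",
]

#: 1 mL/min = 60/1000 L/h
ML_MIN_TO_L_PER_H = 0.06


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics feeding the renal equations and the covariate model."""

    age_years: float
    sex: str  # "male" | "female"
    weight_kg: float
    serum_creatinine_mg_dl: float
    crcl_mL_min: float | None = None  # measured/derived creatinine clearance

    def __post_init__(self) -> None:
        if self.age_years <= 17:
            raise ValueError("adult cohort: age must be > 17 years")
        if self.weight_kg <= 0:
            raise ValueError("weight must be > 0")
        if self.serum_creatinine_mg_dl <= 0:
            raise ValueError("serum creatinine must be > 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


class RenalCategory(Enum):
    """KDIGO GFR categories (mL/min/1.73 m2), lower-inclusive boundaries."""

    G1_normal = "G1_normal"      # >= 90
    G2 = "G2"                    # 60-89
    G3a = "G3a"                  # 45-59
    G3b = "G3b"                  # 30-44
    G4_severe = "G4_severe"      # 15-29
    G5_failure = "G5_failure"    # < 15


def cockcroft_gault(cov: PatientCovariates) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    CrCl = (140 - age) * weight / (72 * Scr), times 0.85 for women.
    """
    crcl = (140.0 - cov.age_years) * cov.weight_kg / (72.0 * cov.serum_creatinine_mg_dl)
    if cov.sex == "female":
        crcl *= 0.85
    if crcl <= 0:
        raise ValueError("computed creatinine clearance is not positive")
    return crcl


def ckd_epi(
    scr_mg_dl: float,
    age_years: float,
    sex: str,
    black: bool = False,
) -> float:
    """2009 CKD-EPI estimated GFR in mL/min/1.73 m2.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] * 1.159 [black]
    with k = 0.7 (female) / 0.9 (male), a = -0.329 (female) / -0.411 (male).
    The race coefficient follows the original 2009 equation and is off by
    default.
    """
    if scr_mg_dl <= 0:
        raise ValueError("serum creatinine must be > 0")
    if age_years <= 0:
        raise ValueError("age must be > 0")
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    r = scr_mg_dl / kappa
    egfr = 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age_years
    egfr *= sex_factor
    if black:
        egfr *= 1.159
    return egfr


_KDIGO_BANDS = (
    (90.0, RenalCategory.G1_normal),
    (60.0, RenalCategory.G2),
    (45.0, RenalCategory.G3a),
    (30.0, RenalCategory.G3b),
    (15.0, RenalCategory.G4_severe),
    (0.0, RenalCategory.G5_failure),
)


def kdigo_category(gfr: float) -> RenalCategory:
    """Map a GFR (mL/min/1.73 m2) to its KDIGO band (lower-inclusive)."""
    if gfr <= 0:
        raise ValueError("GFR must be > 0")
    for lower, cat in _KDIGO_BANDS:
        if gfr >= lower:
            return cat
    raise AssertionError("unreachable")  # pragma: no cover
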