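"""Creatinine clearance (Cockcroft-Gault) and renal-function stratification.

The simulation grid stratifies virtual patients by creatinine clearance into
the five bands used for the dosing recommendations: <10, 10-25, 26-50, 51-90
and 91-140 mL/min.  The integer band labels are mapped to half-open real
intervals so every positive CRCL value falls in exactly one stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["RenalStratum", "STRATA", "cockcroft_gault", "stratum_of"]

#: Factor converting serum creatinine from umol/L to mg/dL.
UMOL_PER_MG_DL = 88.4


@dataclass(frozen=True)
class RenalStratum:
    """One renal-function band: label and half-open CRCL interval [lower, upper)."""

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("stratum bounds must satisfy lower < upper")

    def __contains__(self, crcl: float) -> bool:
        return self.lower <= crcl < self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: Ordered, disjoint strata covering (0, 140] mL/min; the top band is capped
#: at 140 mL/min (values above are clamped into it with a warning).
STRATA = (
    RenalStratum("<10", 0.0, 10.0),
    RenalStratum("10-25", 10.0, 26.0),
    RenalStratum("26-50", 26.0, 51.0),
    RenalStratum("51-90", 51.0, 91.0),
    RenalStratum("91-140", 91.0, 140.0),
)


def cockcroft_gault(
    age: float,
    weight: float,
    scr: float,
    sex: str,
    scr_units: str = "umol/L",
) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault equation.

    Parameters
    ----------
    age : years (adults, 18-120)
    weight : actual body weight, kg
    scr : serum creatinine; umol/L by default (``scr_units="mg/dL"`` accepted)
    sex : "male" or "female" (0.85 multiplier for female)
    """
    if not 18 <= age <= 120:
        raise ValueError(f"age out of supported range [18, 120]: {age}")
    if weight <= 0:
        raise ValueError(f"weight must be positive: {weight}")
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive: {scr}")
    if scr_units == "umol/L":
        scr_mg_dl = scr / UMOL_PER_MG_DL
    elif scr_units == "mg/dL":
        scr_mg_dl = scr
    else:
        raise ValueError(f"unknown creatinine units: {scr_units!r}")
    sex = sex.lower()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female': {sex!r}")
    factor = 0.85 if sex == "female" else 1.0
    return (140.0 - age) * weight / (72.0 * scr_mg_dl) * factor


def stratum_of(crcl: float) -> RenalStratum:
    """The renal stratum containing ``crcl`` (mL/min).

    CRCL above the 140 mL/min cap is clamped into the top stratum with a
    warning (the recommendation grid does not extend beyond 140).
    """
    if crcl <= 0:
        raise ValueError(f"creatinine clearance must be positive: {crcl}")
    for stratum in STRATA:
        if crcl in stratum:
            return stratum
    if crcl == STRATA[-1].upper:  # 140 itself belongs to the capped top band
        return STRATA[-1]
    if crcl > STRATA[-1].upper:
        warnings.warn(
            f"CRCL {crcl:g} mL/min exceeds the {STRATA[-1].label} cap; "
            "clamping to the top stratum",
            stacklevel=2,
        )
        return STRATA[-1]
    raise AssertionError("unreachable: strata cover (0, 140)")  # pragma: no cover
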