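"""Unit conversions, anthropometric indices and GFR (de-)indexing.

Canonical internal units throughout the package: creatinine in mg/dL,
cystatin C in mg/L, GFR in mL/min (non-indexed), with BSA-indexed values
(mL/min/1.73 m2) carried alongside where an equation natively reports them.

Body surface area uses the Du Bois & Du Bois formula,
``BSA = 0.007184 * height_cm**0.725 * weight_kg**0.425``, the standard
choice for indexing GFR to 1.73 m2 and for converting indexed clearances
back to absolute mL/min for drug dosing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

#: Reference body surface area (m2) used for GFR indexing.
BSA_REFERENCE = 1.73

#: Creatinine conversion: 1 mg/dL = 88.42 umol/L (IDMS convention).
UMOL_PER_MG_DL = 88.42


def _require_positive(name: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise DomainError(f"{name} must be strictly positive, got {value!r}")


def bmi(height_cm, weight_kg):
    """Body mass index, kg/m2 = weight / (height in metres)^2."""
    _require_positive("height_cm", height_cm)
    _require_positive("weight_kg", weight_kg)
    height_m = np.asarray(height_cm, dtype=float) / 100.0
    out = np.asarray(weight_kg, dtype=float) / height_m**2
    return float(out) if out.ndim == 0 else out


def bsa_du_bois(height_cm, weight_kg):
    """Du Bois body surface area in m2.

    BSA = 0.007184 * height_cm^0.725 * weight_kg^0.425. Strictly increasing
    in each argument; homogeneous of degree 0.725 in height and 0.425 in
    weight.
    """
    _require_positive("height_cm", height_cm)
    _require_positive("weight_kg", weight_kg)
    out = (
        0.007184
        * np.asarray(height_cm, dtype=float) ** 0.725
        * np.asarray(weight_kg, dtype=float) ** 0.425
    )
    return float(out) if out.ndim == 0 else out


def deindex_gfr(gfr_indexed, bsa):
    """Convert an indexed GFR (mL/min/1.73 m2) to absolute mL/min."""
    _require_positive("bsa", bsa)
    out = np.asarray(gfr_indexed, dtype=float) * np.asarray(bsa, dtype=float) / BSA_REFERENCE
    return float(out) if out.ndim == 0 else out


def reindex_gfr(gfr_nonindexed, bsa):
    """Convert an absolute GFR (mL/min) to BSA-indexed mL/min/1.73 m2.

    Exact inverse of :func:`deindex_gfr`.
    """
    _require_positive("bsa", bsa)
    out = np.asarray(gfr_nonindexed, dtype=float) * BSA_REFERENCE / np.asarray(bsa, dtype=float)
    return float(out) if out.ndim == 0 else out


def creatinine_to_mg_dl(value, unit: str):
    """Convert serum creatinine to mg/dL.

    Parameters
    ----------
    value
        Creatinine concentration, strictly positive.
    unit
        ``"umol_l"`` (divided by 88.42) or ``"mg_dl"`` (passed through).
    """
    _require_positive("creatinine", value)
    if unit == "umol_l":
        out = np.asarray(value, dtype=float) / UMOL_PER_MG_DL
    elif unit == "mg_dl":
        out = np.asarray(value, dtype=float) * 1.0
    else:
        raise ConfigurationError(
            f"unknown creatinine unit {unit!r}; expected 'umol_l' or 'mg_dl'"
        )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Anthropometrics:
    """Height/weight with derived BMI and Du Bois BSA.

    BMI and BSA are pure functions of height and weight and are computed at
    construction; no rounding is applied internally.
    """

    height_cm: float
    weight_kg: float

    def __post_init__(self):
        _require_positive("height_cm", self.height_cm)
        _require_positive("weight_kg", self.weight_kg)

    @property
    def bmi(self) -> float:
        return bmi(self.height_cm, self.weight_kg)

    @property
    def bsa(self) -> float:
        return bsa_du_bois(self.height_cm, self.weight_kg)
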