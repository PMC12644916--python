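"""GFR-estimating equations and the coefficient registry.

Implements the equations evaluated in the analysis:

===================  ========  =====================================
id                   markers   equation
===================  ========  =====================================
ckdepi2009_cr        cr        CKD-EPI 2009 creatinine (no race term)
ckdepi2021_cr        cr        CKD-EPI 2021 creatinine (race-free refit)
ekfc2021_cr          cr        EKFC 2021 creatinine
ckdepi2012_cys       cys       CKD-EPI 2012 cystatin C
ekfc2023_cys         cys       EKFC 2023 cystatin C (sex-free Q)
ckdepi2012_crcys     cr+cys    CKD-EPI 2012 creatinine + cystatin C
ekfc2023_crcys       cr+cys    mean of ekfc2021_cr and ekfc2023_cys
cockcroft_gault      cr        Cockcroft-Gault creatinine clearance
===================  ========  =====================================

All equations except Cockcroft-Gault return BSA-indexed eGFR in
mL/min/1.73 m2; Cockcroft-Gault estimates absolute creatinine clearance in
mL/min (it needs body weight and is never BSA-indexed). No race coefficient
is applied anywhere. Coefficients live in a versioned registry table
(``data/equation_coefficients.csv``) rather than in code, so each constant
can be audited against its source publication and further equations can be
registered without code changes.

CKD-EPI equations are two-piece power laws in the marker rescaled by a knot
``kappa``; EKFC equations are two-piece power laws in the marker rescaled by
a population median ``Q``, with exponent 0.322 below the knot and 1.132
above and a 0.990^(age-40) decay after age 40. Both families are continuous
at the knot and strictly decreasing in each marker.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError, InputError
from .units import deindex_gfr

# ---------------------------------------------------------------------------
# Registry

#: Default selection: the six main comparison equations plus Cockcroft-Gault.
DEFAULT_SELECTION = (
    "ckdepi2009_cr",
    "ekfc2021_cr",
    "ckdepi2012_cys",
    "ekfc2023_cys",
    "ckdepi2012_crcys",
    "ekfc2023_crcys",
    "cockcroft_gault",
)

_EQUATION_META = {
    "ckdepi2009_cr": {"markers": ("cr",), "output_scale": "indexed"},
    "ckdepi2021_cr": {"markers": ("cr",), "output_scale": "indexed"},
    "ekfc2021_cr": {"markers": ("cr",), "output_scale": "indexed"},
    "ckdepi2012_cys": {"markers": ("cys",), "output_scale": "indexed"},
    "ekfc2023_cys": {"markers": ("cys",), "output_scale": "indexed"},
    "ckdepi2012_crcys": {"markers": ("cr", "cys"), "output_scale": "indexed"},
    "ekfc2023_crcys": {"markers": ("cr", "cys"), "output_scale": "indexed"},
    "cockcroft_gault": {"markers": ("cr",), "output_scale": "non_indexed"},
}


def _load_coefficients() -> dict:
    table: dict = {}
    path = resources.files("gfrconcord.data").joinpath("equation_coefficients.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["id"], {})[row["parameter"]] = float(row["value"])
    return table


_COEFFS = _load_coefficients()


def known_equations() -> list[str]:
    """All registered equation identifiers."""
    return list(_EQUATION_META)


def equation_info(equation_id: str) -> dict:
    """Metadata (markers, output scale, coefficients) for one equation."""
    _check_id(equation_id)
    meta = dict(_EQUATION_META[equation_id])
    meta["coefficients"] = dict(_COEFFS.get(equation_id, {}))
    return meta


def _check_id(equation_id: str) -> None:
    if equation_id not in _EQUATION_META:
        raise ConfigurationError(
            f"unknown equation id {equation_id!r}; known ids: {sorted(_EQUATION_META)}"
        )


# ---------------------------------------------------------------------------
# Inputs

@dataclass(frozen=True)
class MarkerPanel:
    """Filtration markers plus the demographics every equation needs.

    scr is serum creatinine in mg/dL, scys serum cystatin C in mg/L; either
    may be absent, but at least one must be present. weight (kg) is required
    only by Cockcroft-Gault.
    """

    age: float
    sex: str
    scr: Optional[float] = None
    scys: Optional[float] = None
    weight: Optional[float] = None

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise InputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age < 18:
            raise DomainError(f"age must be >= 18 years, got {self.age}")
        if self.scr is None and self.scys is None:
            raise InputError("at least one of scr/scys must be present")
        for name in ("scr", "scys", "weight"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be strictly positive, got {v}")

    def require(self, marker: str) -> float:
        value = {"cr": self.scr, "cys": self.scys}[marker]
        if value is None:
            raise InputError(f"marker {marker!r} required but missing from panel")
        return value


@dataclass(frozen=True)
class EquationResult:
    """One equation's output for one determination."""

    equation_id: str
    egfr_indexed: Optional[float]  # mL/min/1.73 m2; None for Cockcroft-Gault
    egfr_nonindexed: Optional[float]  # mL/min; None when no BSA available


# ---------------------------------------------------------------------------
# CKD-EPI family

def _ckdepi_demo_factor(c: dict, age: float, female: bool) -> float:
    return c["age_factor"] ** age * (c["female_factor"] if female else 1.0)


def _ckdepi_cr_variant(variant: str) -> str:
    return {"cr2009": "ckdepi2009_cr", "cr2021": "ckdepi2021_cr",
            "cys2012": "ckdepi2012_cys", "crcys2012": "ckdepi2012_crcys"}[variant]


def ckdepi_egfr(variant: str, panel: MarkerPanel) -> float:
    """CKD-EPI eGFR in mL/min/1.73 m2.

    variant is one of ``cr2009``, ``cr2021``, ``cys2012``, ``crcys2012``.
    """
    try:
        eq_id = _ckdepi_cr_variant(variant)
    except KeyError:
        raise ConfigurationError(f"unknown CKD-EPI variant {variant!r}") from None
    c = _COEFFS[eq_id]
    female = panel.sex == "female"
    demo = _ckdepi_demo_factor(c, panel.age, female)

    if variant in ("cr2009", "cr2021"):
        scr = panel.require("cr")
        kappa = c["kappa_female"] if female else c["kappa_male"]
        alpha = c["alpha_female"] if female else c["alpha_male"]
        r = scr / kappa
        return c["intercept"] * min(r, 1.0) ** alpha * max(r, 1.0) ** c["beta"] * demo
    if variant == "cys2012":
        r = panel.require("cys") / c["kappa"]
        return c["intercept"] * min(r, 1.0) ** c["alpha"] * max(r, 1.0) ** c["beta"] * demo
    # crcys2012
    scr = panel.require("cr")
    scys = panel.require("cys")
    kappa_cr = c["kappa_cr_female"] if female else c["kappa_cr_male"]
    alpha_cr = c["alpha_cr_female"] if female else c["alpha_cr_male"]
    rcr = scr / kappa_cr
    rcys = scys / c["kappa_cys"]
    return (
        c["intercept"]
        * min(rcr, 1.0) ** alpha_cr
        * max(rcr, 1.0) ** c["beta_cr"]
        * min(rcys, 1.0) ** c["alpha_cys"]
        * max(rcys, 1.0) ** c["beta_cys"]
        * demo
    )


# ---------------------------------------------------------------------------
# EKFC family

def _ekfc_q(marker: str, age: float, sex: str) -> float:
    """Population-median marker value Q used to rescale the biomarker."""
    if marker == "cr":
        c = _COEFFS["ekfc2021_cr"]
        return c["q_female"] if sex == "female" else c["q_male"]
    c = _COEFFS["ekfc2023_cys"]
    if age < c["q_age_knot"]:
        return c["q_base"]
    return c["q_base"] + c["q_age_slope"] * (age - c["q_age_knot"])


def ekfc_egfr(marker: str, panel: MarkerPanel) -> float:
    """EKFC eGFR (2021 creatinine or 2023 cystatin C) in mL/min/1.73 m2."""
    if marker not in ("cr", "cys"):
        raise ConfigurationError(f"unknown EKFC marker {marker!r}")
    eq_id = "ekfc2021_cr" if marker == "cr" else "ekfc2023_cys"
    c = _COEFFS[eq_id]
    value = panel.require(marker)
    r = value / _ekfc_q(marker, panel.age, panel.sex)
    alpha = c["alpha_low"] if r < 1.0 else c["alpha_high"]
    out = c["intercept"] / r**alpha
    if panel.age > c["age_knot"]:
        out *= c["age_decay"] ** (panel.age - c["age_knot"])
    return out


def ekfc_crcys_combined(panel: MarkerPanel) -> float:
    """EKFC 2023 combined estimate: arithmetic mean of the cr and cys EKFC eGFRs."""
    return 0.5 * (ekfc_egfr("cr", panel) + ekfc_egfr("cys", panel))


# ---------------------------------------------------------------------------
# Cockcroft-Gault

def cockcroft_gault(panel: MarkerPanel) -> float:
    """Cockcroft-Gault estimated creatinine clearance in mL/min (non-indexed).

    eClcr = (140 - age) * weight / (72 * Scr) * (0.85 if female). Estimates
    creatinine clearance, which exceeds GFR because of tubular secretion.
    """
    if panel.weight is None:
        raise InputError("Cockcroft-Gault requires body weight")
    c = _COEFFS["cockcroft_gault"]
    scr = panel.require("cr")
    out = (c["age_offset"] - panel.age) * panel.weight / (c["denominator"] * scr)
    if panel.sex == "female":
        out *= c["female_factor"]
    return out


# ---------------------------------------------------------------------------
# Dispatch

_DISPATCH = {
    "ckdepi2009_cr": lambda p: ckdepi_egfr("cr2009", p),
    "ckdepi2021_cr": lambda p: ckdepi_egfr("cr2021", p),
    "ckdepi2012_cys": lambda p: ckdepi_egfr("cys2012", p),
    "ckdepi2012_crcys": lambda p: ckdepi_egfr("crcys2012", p),
    "ekfc2021_cr": lambda p: ekfc_egfr("cr", p),
    "ekfc2023_cys": lambda p: ekfc_egfr("cys", p),
    "ekfc2023_crcys": ekfc_crcys_combined,
    "cockcroft_gault": cockcroft_gault,
}


def evaluate(equation_id: str, panel: MarkerPanel) -> float:
    """Evaluate one equation on its native scale (see ``equation_info``)."""
    _check_id(equation_id)
    return _DISPATCH[equation_id](panel)


def evaluate_all(panel: MarkerPanel, anthro=None, selection=DEFAULT_SELECTION) -> list[EquationResult]:
    """Evaluate a selection of equations, returning indexed and absolute values.

    anthro provides the BSA used to de-index BSA-indexed equations; if it is
    None those results carry only the indexed value. Cockcroft-Gault draws
    weight from the panel or, failing that, from anthro.
    """
    if not selection:
        raise ConfigurationError("equation selection must be non-empty")
    results = []
    for eq_id in selection:
        _check_id(eq_id)
        p = panel
        if eq_id == "cockcroft_gault" and panel.weight is None and anthro is not None:
            p = MarkerPanel(age=panel.age, sex=panel.sex, scr=panel.scr,
                            scys=panel.scys, weight=anthro.weight_kg)
        value = _DISPATCH[eq_id](p)
        if _EQUATION_META[eq_id]["output_scale"] == "indexed":
            nonindexed = deindex_gfr(value, anthro.bsa) if anthro is not None else None
            results.append(EquationResult(eq_id, value, nonindexed))
        else:
            results.append(EquationResult(eq_id, None, value))
    return results


# ---------------------------------------------------------------------------
# Marker inversion (used by the cohort simulator)

_INVERTIBLE = ("ckdepi2009_cr", "ckdepi2021_cr", "ckdepi2012_cys",
               "ekfc2021_cr", "ekfc2023_cys")


def _eval_single_marker(equation_id: str, m: float, age: float, sex: str) -> float:
    marker = _EQUATION_META[equation_id]["markers"][0]
    kwargs = {"scr": m} if marker == "cr" else {"scys": m}
    return evaluate(equation_id, MarkerPanel(age=age, sex=sex, **kwargs))


def invert_marker(equation_id: str, target_egfr: float, age: float, sex: str) -> float:
    """Marker value at which a single-marker equation returns target_egfr.

    Solves the piecewise closed form branch by branch, keeping the solution
    consistent with its branch condition; both branches coincide at the knot.
    Falls back to root bracketing if the closed form does not reproduce the
    target to 1e-10 relative (it should never trigger for the registered
    forms, all of which are strictly decreasing bijections of (0, inf)).
    """
    if equation_id not in _INVERTIBLE:
        raise ConfigurationError(
            f"{equation_id!r} is not a single-marker invertible equation; "
            f"choose one of {_INVERTIBLE}"
        )
    if not target_egfr > 0:
        raise DomainError(f"target eGFR must be positive, got {target_egfr}")
    female = sex == "female"
    c = _COEFFS[equation_id]

    if equation_id.startswith("ckdepi"):
        demo = _ckdepi_demo_factor(c, age, female)
        knot_value = c["intercept"] * demo  # eGFR when marker == kappa
        if equation_id == "ckdepi2012_cys":
            kappa, alpha = c["kappa"], c["alpha"]
        else:
            kappa = c["kappa_female"] if female else c["kappa_male"]
            alpha = c["alpha_female"] if female else c["alpha_male"]
        # marker <= kappa  <=>  eGFR >= knot_value (exponents negative)
        expo = alpha if target_egfr >= knot_value else c["beta"]
        m = kappa * (target_egfr / knot_value) ** (1.0 / expo)
    else:  # EKFC family
        marker = _EQUATION_META[equation_id]["markers"][0]
        q = _ekfc_q(marker, age, sex)
        decay = c["age_decay"] ** max(age - c["age_knot"], 0.0)
        knot_value = c["intercept"] * decay  # eGFR when marker == Q
        alpha = c["alpha_low"] if target_egfr > knot_value else c["alpha_high"]
        m = q * (knot_value / target_egfr) ** (1.0 / alpha)

    achieved = _eval_single_marker(equation_id, m, age, sex)
    if abs(achieved - target_egfr) / target_egfr > 1e-10:
        m = brentq(
            lambda x: _eval_single_marker(equation_id, x, age, sex) - target_egfr,
            1e-6, 1e4, xtol=1e-14, rtol=8.9e-16,
        )
    return m
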