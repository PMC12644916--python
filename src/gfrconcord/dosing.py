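"""Carboplatin dosing via the Calvert formula and dosing-error classification.

Carboplatin is dosed to a target plasma AUC (mg/mL/min) using
``dose (mg) = AUC * (GFR + 25)`` with the GFR input capped at 125 mL/min.
Given a measured GFR (the reference) and an equation's estimate, the AUC a
patient would actually achieve if dosed on the estimate is

    achieved AUC = target AUC * dose(eGFR) / dose(mGFR)

An achieved AUC above 6 mg/mL/min is classed as overdose and below 4 as
underdose (strict inequalities); at the conventional target of 5 these
bounds are +/-20% of target. Determinations with mGFR < 30 mL/min are
excluded from dosing analyses (carboplatin would be contraindicated).

GFR enters in absolute mL/min (non-indexed) throughout. By default the
125 mL/min cap is applied to both the estimated and the reference dose;
``cap_reference=False`` leaves the reference (mGFR) dose uncapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError

#: Upper GFR limit (mL/min) applied inside the Calvert formula.
GFR_CAP = 125.0

#: Default target AUC (mg/mL/min) and the achieved-AUC bounds.
TARGET_AUC = 5.0
AUC_BOUNDS = (4.0, 6.0)

#: mGFR below this (mL/min) is excluded from dosing analyses.
MGFR_DOSING_FLOOR = 30.0


def calvert_dose(gfr, target_auc: float = TARGET_AUC, cap: float = GFR_CAP):
    """Carboplatin dose in mg: target_auc * (min(gfr, cap) + 25)."""
    if not target_auc > 0:
        raise DomainError(f"target AUC must be positive, got {target_auc}")
    g = np.asarray(gfr, dtype=float)
    if np.any(g < 0):
        raise DomainError("GFR must be non-negative")
    out = target_auc * (np.minimum(g, cap) + 25.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DoseAssessment:
    gfr_used_est: float  # mL/min after cap
    gfr_used_ref: float
    dose_est: float  # mg
    dose_ref: float
    achieved_auc: float  # mg/mL/min
    category: str  # overdose / acceptable / underdose
    target_auc: float


def assess_dose(
    mgfr: float,
    egfr: float,
    target_auc: float = TARGET_AUC,
    auc_bounds: tuple = AUC_BOUNDS,
    cap_reference: bool = True,
) -> DoseAssessment:
    """Classify the dosing consequence of using egfr instead of mgfr."""
    dose_est = calvert_dose(egfr, target_auc)
    dose_ref = calvert_dose(mgfr, target_auc, cap=GFR_CAP if cap_reference else np.inf)
    achieved = target_auc * dose_est / dose_ref
    lo, hi = auc_bounds
    if achieved > hi:
        category = "overdose"
    elif achieved < lo:
        category = "underdose"
    else:
        category = "acceptable"
    return DoseAssessment(
        gfr_used_est=min(float(egfr), GFR_CAP),
        gfr_used_ref=min(float(mgfr), GFR_CAP) if cap_reference else float(mgfr),
        dose_est=float(dose_est),
        dose_ref=float(dose_ref),
        achieved_auc=float(achieved),
        category=category,
        target_auc=target_auc,
    )


def traffic_light(rate_percent: float) -> str:
    """Dose-error traffic light: Green <=5%, Amber >5-10%, Red >10%."""
    if rate_percent <= 5:
        return "Green"
    if rate_percent <= 10:
        return "Amber"
    return "Red"


def _rates(achieved: np.ndarray, auc_bounds: tuple) -> dict:
    lo, hi = auc_bounds
    n = achieved.size
    over = 100.0 * np.count_nonzero(achieved > hi) / n
    under = 100.0 * np.count_nonzero(achieved < lo) / n
    return {
        "n": int(n),
        "overdose_pct": over,
        "underdose_pct": under,
        "acceptable_pct": 100.0 - over - under,
        "overdose_light": traffic_light(over),
        "underdose_light": traffic_light(under),
    }


def dose_error_rates(
    mgfr,
    egfr,
    target_auc: float = TARGET_AUC,
    strata=None,
    auc_bounds: tuple = AUC_BOUNDS,
    cap_reference: bool = True,
    mgfr_floor: float = MGFR_DOSING_FLOOR,
) -> pd.DataFrame:
    """Overdose/underdose percentages, overall or per stratum.

    Determinations with mGFR below mgfr_floor are dropped (their count is
    reported in the ``n_excluded_low_mgfr`` attribute of the result). Empty
    strata are reported with n = 0 and no percentages.
    """
    m = np.asarray(mgfr, dtype=float)
    e = np.asarray(egfr, dtype=float)
    keep = m >= mgfr_floor
    n_excluded = int(np.count_nonzero(~keep))
    m, e = m[keep], e[keep]
    dose_est = calvert_dose(e, target_auc)
    dose_ref = calvert_dose(m, target_auc, cap=GFR_CAP if cap_reference else np.inf)
    achieved = target_auc * dose_est / dose_ref

    rows = []
    if strata is None:
        rows.append({"stratum": "overall", **_rates(achieved, auc_bounds)})
    else:
        lab = np.asarray(strata)[keep]
        for key in np.unique(lab):
            sel = lab == key
            if not sel.any():
                rows.append({"stratum": key, "n": 0})
            else:
                rows.append({"stratum": key, **_rates(achieved[sel], auc_bounds)})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded_low_mgfr"] = n_excluded
    return out
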