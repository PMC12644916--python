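"""Cohort ingestion, eligibility screening and derived analysis fields.

The atomic analysis record is one *determination*: a measured-GFR event
with concurrent creatinine and cystatin C (drawn on the same day, within 30
days of the mGFR), anthropometrics measured within 30 days of the mGFR, and
an mGFR date falling within two years after the cancer diagnosis.
Non-indexed mGFR outside (0, 150] mL/min is treated as implausible.
Repeated determinations of one person are kept as separate records.

Every input row ends up exactly once as either retained or excluded with
the first failing rule, checked in a fixed order:

    schema -> lab window -> anthro window -> diagnosis window -> mGFR plausibility

All windows are inclusive at the boundary (|delta| <= 30 days qualifies;
"within 2 years" means mGFR date minus diagnosis date in [0, 730] days);
widths and bounds are configurable through :class:`CohortConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .units import bmi, bsa_du_bois, creatinine_to_mg_dl, deindex_gfr, reindex_gfr

REQUIRED_COLUMNS = (
    "id", "age_years", "sex", "height_cm", "weight_kg", "date_anthro",
    "scr_value", "scr_unit", "scys_mg_l", "date_labs",
    "mgfr_indexed", "mgfr_nonindexed", "date_mgfr", "date_cancer_dx",
    "cancer_type", "metastatic", "steroid_use",
)

_SEXES = ("female", "male")
_METASTATIC = ("metastatic", "not_metastatic", "unknown")
_BMI_EDGES = (20.0, 25.0, 30.0)
BMI_LABELS = ("<20", "20-<25", "25-<30", ">=30")


@dataclass(frozen=True)
class CohortConfig:
    """Eligibility windows and plausibility bounds (all inclusive)."""

    lab_window_days: int = 30
    anthro_window_days: int = 30
    dx_window_days: int = 730
    mgfr_min: float = 0.0  # exclusive lower bound
    mgfr_max: float = 150.0  # inclusive upper bound
    mgfr_consistency_tol: float = 0.01  # when both indexed and non-indexed given


def bmi_category(bmi_value):
    """Left-closed BMI bins: <20, 20-<25, 25-<30, >=30 kg/m2."""
    idx = np.digitize(np.asarray(bmi_value, dtype=float), _BMI_EDGES, right=False)
    out = np.asarray(BMI_LABELS)[idx]
    return str(out) if out.ndim == 0 else out


def read_cohort(path_or_buffer, sep: str = ",") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and type a cohort table; collect unparseable rows.

    Returns (records, schema_exclusions). Records carry creatinine converted
    to mg/dL (column ``scr_mg_dl``); rows with malformed values are dropped
    into the exclusion frame with rule ``schema`` and a per-field reason.
    Missing required columns raise :class:`SchemaError`.
    """
    raw = pd.read_csv(path_or_buffer, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    raw = raw.mask(raw == "")
    if "determination_id" not in raw.columns:
        raw = raw.assign(determination_id=[f"D{i:05d}" for i in range(len(raw))])

    reasons = pd.Series("", index=raw.index, dtype=object)

    def flag(mask, reason):
        mask = mask & (reasons == "")
        reasons[mask] = reason

    df = raw.copy()
    for col in ("age_years", "height_cm", "weight_kg", "scr_value", "scys_mg_l",
                "mgfr_indexed", "mgfr_nonindexed"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = raw[col].notna() & df[col].isna()
        flag(bad, f"unparseable numeric value in {col}")
    for col in ("date_anthro", "date_labs", "date_mgfr", "date_cancer_dx"):
        df[col] = pd.to_datetime(df[col], errors="coerce", format="%Y-%m-%d")
        flag(raw[col].notna() & df[col].isna(), f"unparseable date in {col}")

    flag(~df["sex"].isin(_SEXES), "sex not in {female, male}")
    flag(df["age_years"].isna() | (df["age_years"] < 18), "age missing or < 18")
    flag(~df["scr_unit"].isin(("umol_l", "mg_dl")), "unknown creatinine unit")
    flag(df["scr_value"].isna() | (df["scr_value"] <= 0), "missing/non-positive creatinine")
    flag(df["scys_mg_l"].isna() | (df["scys_mg_l"] <= 0), "missing/non-positive cystatin C")
    flag(df["date_labs"].isna(), "missing lab date")
    flag(df["date_mgfr"].isna(), "missing mGFR date")
    flag(df["date_cancer_dx"].isna(), "missing cancer diagnosis date")
    flag(df["mgfr_indexed"].isna() & df["mgfr_nonindexed"].isna(), "no mGFR value")
    df["metastatic"] = df["metastatic"].fillna("unknown")
    flag(~df["metastatic"].isin(_METASTATIC), "metastatic not in allowed categories")
    steroid = df["steroid_use"].astype(str).str.lower().map(
        {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False}
    )
    flag(df["steroid_use"].notna() & steroid.isna(), "unparseable steroid_use flag")
    df["steroid_use"] = steroid.fillna(False).astype(bool)

    ok = reasons == ""
    records = df[ok].copy()
    records["scr_mg_dl"] = [
        creatinine_to_mg_dl(v, u)
        for v, u in zip(records["scr_value"], records["scr_unit"])
    ]
    exclusions = pd.DataFrame({
        "determination_id": df.loc[~ok, "determination_id"],
        "rule": "schema",
        "reason": reasons[~ok],
    })
    return records, exclusions


def apply_eligibility(
    records: pd.DataFrame, config: CohortConfig = CohortConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply window and plausibility rules; derive analysis fields.

    Returns (determinations, exclusion_log). Every record lands exactly once
    in one of the two frames; exclusions carry the first failing rule.
    Retained records gain bmi, bsa, bmi_category and both mGFR scales.
    Idempotent: re-applying to the retained frame changes nothing.
    """
    df = records.copy()
    rule = pd.Series("", index=df.index, dtype=object)
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask, rule_id, why):
        mask = mask & (rule == "")
        rule[mask] = rule_id
        reason[mask] = why

    lab_delta = (df["date_labs"] - df["date_mgfr"]).dt.days.abs()
    flag(lab_delta.isna() | (lab_delta > config.lab_window_days),
         "lab_window", f"labs not within {config.lab_window_days} days of mGFR")

    anthro_missing = (
        df["height_cm"].isna() | (df["height_cm"] <= 0)
        | df["weight_kg"].isna() | (df["weight_kg"] <= 0)
        | df["date_anthro"].isna()
    )
    anthro_delta = (df["date_anthro"] - df["date_mgfr"]).dt.days.abs()
    flag(anthro_missing | (anthro_delta > config.anthro_window_days),
         "anthro_window",
         f"height/weight missing or not within {config.anthro_window_days} days of mGFR")

    dx_delta = (df["date_mgfr"] - df["date_cancer_dx"]).dt.days
    flag(dx_delta.isna() | (dx_delta < 0) | (dx_delta > config.dx_window_days),
         "dx_window", f"mGFR not within {config.dx_window_days} days after diagnosis")

    # Plausibility on the non-indexed scale; non-indexed wins when both are
    # supplied, with a consistency check against the indexed value via BSA.
    ok_so_far = rule == ""
    bsa = pd.Series(np.nan, index=df.index)
    bsa[ok_so_far] = bsa_du_bois(df.loc[ok_so_far, "height_cm"],
                                 df.loc[ok_so_far, "weight_kg"])
    mgfr_ni = df["mgfr_nonindexed"].copy()
    only_indexed = mgfr_ni.isna() & df["mgfr_indexed"].notna()
    mgfr_ni[only_indexed] = deindex_gfr(df.loc[only_indexed, "mgfr_indexed"],
                                        bsa[only_indexed].fillna(1.73))
    both = df["mgfr_nonindexed"].notna() & df["mgfr_indexed"].notna() & ok_so_far
    implied = deindex_gfr(df.loc[both, "mgfr_indexed"], bsa[both])
    inconsistent = (implied - df.loc[both, "mgfr_nonindexed"]).abs() \
        > config.mgfr_consistency_tol * df.loc[both, "mgfr_nonindexed"]
    flag(inconsistent.reindex(df.index, fill_value=False),
         "mgfr_plausibility",
         f"indexed and non-indexed mGFR disagree by more than "
         f"{100 * config.mgfr_consistency_tol:g}%")
    flag(mgfr_ni.isna() | (mgfr_ni <= config.mgfr_min) | (mgfr_ni > config.mgfr_max),
         "mgfr_plausibility",
         f"non-indexed mGFR outside ({config.mgfr_min:g}, {config.mgfr_max:g}] mL/min")

    keep = rule == ""
    out = df[keep].copy()
    out["bmi"] = bmi(out["height_cm"], out["weight_kg"])
    out["bsa"] = bsa[keep]
    out["bmi_category"] = bmi_category(out["bmi"])
    out["mgfr"] = mgfr_ni[keep]
    out["mgfr_indexed_derived"] = reindex_gfr(out["mgfr"], out["bsa"])

    exclusions = pd.DataFrame({
        "determination_id": df.loc[~keep, "determination_id"],
        "rule": rule[~keep],
        "reason": reason[~keep],
    })
    return out, exclusions


def load_cohort(path_or_buffer, config: CohortConfig = CohortConfig(), sep: str = ","):
    """read_cohort + apply_eligibility; exclusion logs concatenated."""
    records, schema_excl = read_cohort(path_or_buffer, sep=sep)
    determinations, elig_excl = apply_eligibility(records, config)
    log = pd.concat([schema_excl, elig_excl], ignore_index=True)
    return determinations, log
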