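"""Synthetic per-determination cohorts with explicit non-GFR determinants.

The generator draws a *true* absolute GFR for each determination, inverts a
reference single-marker equation at that GFR to obtain the creatinine and
cystatin C a perfectly GFR-determined marker would show, and then perturbs
each marker with explicit, independently switchable non-GFR factors:

* a lognormal *muscle* factor on creatinine, with a negative mean shift in
  metastatic disease (muscle loss lowers creatinine and inflates
  creatinine-based eGFR);
* a lognormal *inflammation* factor on cystatin C, with positive mean
  shifts under systemic glucocorticoids and in metastatic disease (raised
  cystatin C deflates cystatin-based eGFR);
* multiplicative assay error on both markers;
* lognormal biologic variability on the observed mGFR around the true GFR.

Demographic and clinical margins default to the study conditions being
emulated: 38.5% female, age ~ N(68, 9) truncated to [18, 95], BMI ~
N(25.3, 4.5) truncated to [14, 55], true GFR ~ N(75, 30) mL/min truncated
to (0, 150], 17% metastatic, 16.7% unknown stage, 33.8% glucocorticoid use.
The (true GFR, biologic noise) pair is rejection-sampled jointly so the
*observed* mGFR also lies in (0, 150] and generated tables pass the
plausibility screen with zero exclusions.

With all noise terms zero, every equation matched to its reference inverts
exactly: eGFR == mGFR record by record, which pins down the whole
downstream pipeline (P30 = P15 = 100%, zero bias, zero dose errors).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .equations import invert_marker
from .units import bsa_du_bois, reindex_gfr, UMOL_PER_MG_DL

INDEX_DATE = "2020-06-15"


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate the target study conditions."""

    n: int = 1000
    seed: int = 0
    female_frac: float = 0.385
    age_mean: float = 68.0
    age_sd: float = 9.0
    age_bounds: tuple = (18.0, 95.0)
    bmi_mean: float = 25.3
    bmi_sd: float = 4.5
    bmi_bounds: tuple = (14.0, 55.0)
    height_mean: dict = field(default_factory=lambda: {"female": 165.0, "male": 178.0})
    height_sd: float = 7.0
    mgfr_mean: float = 75.0
    mgfr_sd: float = 30.0
    mgfr_bounds: tuple = (0.0, 150.0)  # exclusive lower, inclusive upper
    metastatic_frac: float = 0.17
    unknown_frac: float = 0.167
    steroid_frac: float = 0.338
    # Non-GFR determinants (log scale) and measurement error.
    sigma_muscle: float = 0.15
    delta_muscle: float = -0.15  # metastatic shift; < 0 lowers creatinine
    sigma_inflam: float = 0.15
    delta_inflam: float = 0.12  # per steroid/metastatic flag; > 0 raises cystatin C
    assay_cv: float = 0.04
    mgfr_biologic_cv: float = 0.05
    # Reference equations inverted to generate the markers.
    cr_reference: str = "ekfc2021_cr"
    cys_reference: str = "ekfc2023_cys"
    messy: bool = False  # emit some rows violating eligibility, to exercise the log

    def validate(self) -> None:
        for name in ("female_frac", "metastatic_frac", "unknown_frac", "steroid_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.metastatic_frac + self.unknown_frac > 1.0:
            raise ConfigurationError("metastatic_frac + unknown_frac must be <= 1")
        for name in ("age_sd", "bmi_sd", "height_sd", "mgfr_sd", "sigma_muscle",
                     "sigma_inflam", "assay_cv", "mgfr_biologic_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")


def noise_free(params: SimulationParams) -> SimulationParams:
    """Copy of params with every noise/shift term set to zero."""
    return replace(params, sigma_muscle=0.0, delta_muscle=0.0, sigma_inflam=0.0,
                   delta_inflam=0.0, assay_cv=0.0, mgfr_biologic_cv=0.0)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
                              sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(params: SimulationParams = SimulationParams()) -> pd.DataFrame:
    """Generate a cohort table compatible with :func:`gfrconcord.cohort.read_cohort`.

    The table also carries a ``true_gfr`` column (mL/min) that the reader
    ignores; it is the generator's ground truth, handy for diagnostics.
    Identical params (including seed) give an identical table.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    female = rng.random(n) < params.female_frac
    sex = np.where(female, "female", "male")
    age = _truncated_normal(rng, params.age_mean, params.age_sd, *params.age_bounds, n)
    height_mean = np.where(female, params.height_mean["female"], params.height_mean["male"])
    height = _truncated_normal(rng, height_mean, params.height_sd, 120.0, 220.0, n)
    bmi = _truncated_normal(rng, params.bmi_mean, params.bmi_sd, *params.bmi_bounds, n)
    weight = bmi * (height / 100.0) ** 2
    bsa = bsa_du_bois(height, weight)

    u = rng.random(n)
    metastatic = np.where(
        u < params.metastatic_frac, "metastatic",
        np.where(u < params.metastatic_frac + params.unknown_frac, "unknown",
                 "not_metastatic"),
    )
    steroid = rng.random(n) < params.steroid_frac

    # True GFR and observed mGFR, jointly resampled into the plausible range.
    lo, hi = params.mgfr_bounds
    true_gfr = np.empty(n)
    mgfr_obs = np.empty(n)
    pending = np.ones(n, dtype=bool)
    while pending.any():
        k = pending.sum()
        g = rng.normal(params.mgfr_mean, params.mgfr_sd, k)
        obs = g * np.exp(rng.normal(0.0, params.mgfr_biologic_cv, k))
        ok = (g > lo) & (g <= hi) & (obs > lo) & (obs <= hi)
        idx = np.flatnonzero(pending)[ok]
        true_gfr[idx] = g[ok]
        mgfr_obs[idx] = obs[ok]
        pending[idx] = False

    true_gfr_indexed = reindex_gfr(true_gfr, bsa)
    scr_true = np.array([
        invert_marker(params.cr_reference, g, a, s)
        for g, a, s in zip(true_gfr_indexed, age, sex)
    ])
    scys_true = np.array([
        invert_marker(params.cys_reference, g, a, s)
        for g, a, s in zip(true_gfr_indexed, age, sex)
    ])

    eps_muscle = rng.normal(params.delta_muscle * (metastatic == "metastatic"),
                            params.sigma_muscle)
    eps_inflam = rng.normal(
        params.delta_inflam * (steroid.astype(float) + (metastatic == "metastatic")),
        params.sigma_inflam,
    )
    scr = scr_true * np.exp(eps_muscle) * np.exp(rng.normal(0.0, params.assay_cv, n))
    scys = scys_true * np.exp(eps_inflam) * np.exp(rng.normal(0.0, params.assay_cv, n))

    index = pd.Timestamp(INDEX_DATE)
    df = pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(n)],
        "determination_id": [f"D{i:05d}" for i in range(n)],
        "age_years": age,
        "sex": sex,
        "height_cm": height,
        "weight_kg": weight,
        "date_anthro": index.strftime("%Y-%m-%d"),
        "scr_value": scr * UMOL_PER_MG_DL,  # emitted in umol/L, as Swedish labs report
        "scr_unit": "umol_l",
        "scys_mg_l": scys,
        "date_labs": index.strftime("%Y-%m-%d"),
        "mgfr_indexed": reindex_gfr(mgfr_obs, bsa),
        "mgfr_nonindexed": mgfr_obs,
        "date_mgfr": index.strftime("%Y-%m-%d"),
        "date_cancer_dx": (index - pd.Timedelta(days=100)).strftime("%Y-%m-%d"),
        "cancer_type": rng.choice(
            ["bladder", "lung", "colorectal", "kidney", "other"], n,
            p=[0.33, 0.23, 0.13, 0.07, 0.24]),
        "metastatic": metastatic,
        "steroid_use": steroid.astype(int),
        "true_gfr": true_gfr,
    })

    if params.messy:
        df = _make_messy(df, rng)
    return df


def _make_messy(df: pd.DataFrame, rng) -> pd.DataFrame:
    """Inject eligibility violations into ~10% of rows (one rule each)."""
    df = df.copy()
    n = len(df)
    k = max(1, n // 10)
    victims = rng.choice(n, size=min(4 * k, n), replace=False)
    index = pd.Timestamp(INDEX_DATE)
    quarters = np.array_split(victims, 4)
    df.iloc[quarters[0], df.columns.get_loc("date_labs")] = \
        (index - pd.Timedelta(days=45)).strftime("%Y-%m-%d")
    df.iloc[quarters[1], df.columns.get_loc("date_anthro")] = \
        (index + pd.Timedelta(days=60)).strftime("%Y-%m-%d")
    df.iloc[quarters[2], df.columns.get_loc("date_cancer_dx")] = \
        (index - pd.Timedelta(days=900)).strftime("%Y-%m-%d")
    df.iloc[quarters[3], df.columns.get_loc("mgfr_nonindexed")] = 155.0
    df.iloc[quarters[3], df.columns.get_loc("mgfr_indexed")] = np.nan
    return df


def cohort_to_csv(df: pd.DataFrame, path=None):
    """Write a simulated cohort as delimited text (reader-compatible)."""
    if path is None:
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    df.to_csv(path, index=False)
    return None


def make_fixture(kind: str) -> pd.DataFrame:
    """Tiny deterministic hand-written tables for the three test domains.

    ``eligibility``: 9 rows — 4 retained, one violation of each screening
    rule (schema, lab window, anthro window, diagnosis window, plausibility).
    ``dosing``: 3 (mgfr, egfr) rows with known dose outcomes.
    ``concordance``: 4 (egfr, mgfr) pairs with P30 = 75%.
    """
    if kind == "eligibility":
        base = dict(age_years="70", sex="male", height_cm="175", weight_kg="80",
                    date_anthro="2020-06-15", scr_value="88.42", scr_unit="umol_l",
                    scys_mg_l="1.0", date_labs="2020-06-15", mgfr_indexed="",
                    mgfr_nonindexed="75", date_mgfr="2020-06-15",
                    date_cancer_dx="2020-03-01", cancer_type="lung",
                    metastatic="not_metastatic", steroid_use="0")
        rows = []
        for i in range(4):  # retained
            rows.append({**base, "id": f"K{i}"})
        rows.append({**base, "id": "X_schema", "sex": "unknown"})
        rows.append({**base, "id": "X_lab", "date_labs": "2020-07-16"})  # +31 d
        rows.append({**base, "id": "X_anthro", "height_cm": ""})
        rows.append({**base, "id": "X_dx", "date_cancer_dx": "2018-01-01"})
        rows.append({**base, "id": "X_mgfr", "mgfr_nonindexed": "150.5"})
        return pd.DataFrame(rows)
    if kind == "dosing":
        return pd.DataFrame({
            "mgfr": [80.0, 70.0, 80.0],
            "egfr": [80.0, 95.0, 50.0],
            "expected_category": ["acceptable", "overdose", "underdose"],
        })
    if kind == "concordance":
        return pd.DataFrame({
            "egfr": [70.0, 50.0, 100.0, 130.0],
            "mgfr": [100.0, 100.0, 100.0, 100.0],
        })
    raise ConfigurationError(f"unknown fixture kind {kind!r}")
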