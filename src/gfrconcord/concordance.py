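"""Agreement statistics between estimated and measured GFR.

Implements the standard method-comparison toolkit for GFR estimating
equations: P30/P15 accuracy (share of determinations whose estimate falls
within +/-30% / +/-15% of measured GFR), bias (median of eGFR - mGFR) and
precision (interquartile range of those differences), Bland-Altman pairs,
and classification agreement across clinical GFR bands.

Conventions (all configurable where noted):

* P30/P15 boundaries are inclusive: |e - m| <= tol * m counts as within.
* Quantiles (median, IQR, Bland-Altman percentiles) use linear
  interpolation, the numpy default.
* GFR bands are left-closed, right-open: [0,30), [30,45), [45,60),
  [60,90), [90,120), [120,inf), i.e. <30, 30-44, 45-59, 60-89, 90-119, 120+.
* Grade boundaries assign exact threshold values to the better class for
  P30 (80 -> acceptable; optimal requires > 90) and to the smaller class
  for bias (|bias| = 5 -> small, = 10 -> medium).

Because the P30/P15 criterion is a ratio, it is invariant to BSA
de-indexing applied to both members of a pair: indexed and non-indexed
series give identical P30/P15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, EmptySeriesError

#: Interior band edges (mL/min) of the six clinical GFR categories.
BAND_EDGES = (30.0, 45.0, 60.0, 90.0, 120.0)

BAND_LABELS = ("<30", "30-44", "45-59", "60-89", "90-119", "120+")


def _as_pairs(egfr, mgfr):
    e = np.asarray(egfr, dtype=float)
    m = np.asarray(mgfr, dtype=float)
    if e.shape != m.shape:
        raise ValueError("egfr and mgfr must have identical shape")
    if e.size == 0:
        raise EmptySeriesError("statistic undefined on an empty paired series")
    if not np.all(m > 0):
        raise DomainError("mGFR must be strictly positive for every pair")
    return e, m


def p_within(egfr, mgfr, tol: float = 0.30) -> float:
    """Percentage of pairs with |eGFR - mGFR| <= tol * mGFR (inclusive)."""
    if not tol > 0:
        raise DomainError(f"tol must be positive, got {tol}")
    e, m = _as_pairs(egfr, mgfr)
    return 100.0 * np.count_nonzero(np.abs(e - m) <= tol * m) / e.size


def bias_precision(egfr, mgfr) -> tuple[float, float]:
    """(median of eGFR - mGFR, IQR of eGFR - mGFR), both in mL/min."""
    e, m = _as_pairs(egfr, mgfr)
    d = e - m
    q1, q3 = np.percentile(d, [25, 75])
    return float(np.median(d)), float(q3 - q1)


def grade_p30(p30: float) -> str:
    """KDIGO-style accuracy grade: <80 unacceptable, 80-90 acceptable, >90 optimal."""
    if p30 > 90:
        return "optimal"
    if p30 >= 80:
        return "acceptable"
    return "unacceptable"


def grade_bias(bias: float) -> str:
    """|bias| <= 5 small, <= 10 medium, > 10 mL/min large."""
    a = abs(bias)
    if a <= 5:
        return "small"
    if a <= 10:
        return "medium"
    return "large"


@dataclass(frozen=True)
class ConcordanceSummary:
    n: int
    p30: float
    p15: float
    bias_median: float
    precision_iqr: float
    p30_grade: str
    bias_grade: str


def summarize(egfr, mgfr) -> ConcordanceSummary:
    """Full accuracy/bias/precision summary for one equation's paired series."""
    e, m = _as_pairs(egfr, mgfr)
    p30 = p_within(e, m, 0.30)
    p15 = p_within(e, m, 0.15)
    bias, iqr = bias_precision(e, m)
    return ConcordanceSummary(
        n=e.size, p30=p30, p15=p15, bias_median=bias, precision_iqr=iqr,
        p30_grade=grade_p30(p30), bias_grade=grade_bias(bias),
    )


def band_of(value, edges=BAND_EDGES):
    """Index of the left-closed GFR band containing value (mL/min)."""
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise DomainError("GFR must be non-negative")
    out = np.digitize(v, edges, right=False)
    return int(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BandTable:
    """Row-normalised eGFR-vs-mGFR band contingency table.

    rows are mGFR bands, columns eGFR bands; percentages normalise each row
    to 100 (rows with zero count are all-zero). percent_agreement is the
    share of all pairs on the diagonal, computed on raw counts.
    """

    edges: tuple
    labels: tuple
    counts: np.ndarray  # (6, 6) raw pair counts
    row_percent: np.ndarray  # (6, 6) row percentages
    row_counts: np.ndarray  # (6,)
    percent_agreement: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.row_percent, index=list(self.labels),
                            columns=list(self.labels))


def contingency(egfr, mgfr, edges=BAND_EDGES) -> BandTable:
    """Band classification agreement table (rows mGFR, columns eGFR)."""
    e, m = _as_pairs(egfr, mgfr)
    nb = len(edges) + 1
    eb = band_of(e, edges)
    mb = band_of(m, edges)
    counts = np.zeros((nb, nb), dtype=int)
    np.add.at(counts, (mb, eb), 1)
    row_counts = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_percent = np.where(
            row_counts[:, None] > 0, 100.0 * counts / row_counts[:, None], 0.0
        )
    agreement = 100.0 * np.trace(counts) / e.size
    return BandTable(tuple(edges), BAND_LABELS[:nb], counts, row_percent,
                     row_counts, agreement)


def stratify(egfr, mgfr, labels, valid_keys=None) -> dict:
    """Per-subgroup ConcordanceSummary keyed by the subgroup label.

    labels is a vector of subgroup labels aligned with the pairs; subgroup
    n's partition the total. valid_keys, when given, restricts which label
    values are allowed (unknown values raise a configuration error).
    """
    e, m = _as_pairs(egfr, mgfr)
    lab = np.asarray(labels)
    if lab.shape != e.shape:
        raise ValueError("labels must align with the pairs")
    if valid_keys is not None:
        unknown = set(np.unique(lab)) - set(valid_keys)
        if unknown:
            raise ConfigurationError(f"unknown subgroup labels: {sorted(unknown)}")
    return {key: summarize(e[lab == key], m[lab == key]) for key in np.unique(lab)}


def bland_altman(egfr, mgfr) -> tuple[pd.DataFrame, dict]:
    """Plot-ready Bland-Altman table and summary.

    Returns (table, summary): table has columns ``mean`` ((e+m)/2) and
    ``difference`` (e-m); summary holds the median bias, IQR and the
    empirical 2.5th/97.5th percentiles of the differences.
    """
    e, m = _as_pairs(egfr, mgfr)
    d = e - m
    table = pd.DataFrame({"mean": (e + m) / 2.0, "difference": d})
    lo, q1, q3, hi = np.percentile(d, [2.5, 25, 75, 97.5])
    summary = {
        "bias_median": float(np.median(d)),
        "precision_iqr": float(q3 - q1),
        "p2_5": float(lo),
        "p97_5": float(hi),
        "n": int(e.size),
    }
    return table, summary
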