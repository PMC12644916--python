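import numpy as np
import pytest

from gfrconcord import (
    band_of, bias_precision, bland_altman, contingency, p_within, stratify,
    summarize,
)
from gfrconcord.concordance import grade_bias, grade_p30
from gfrconcord.errors import ConfigurationError, DomainError, EmptySeriesError
from gfrconcord.synthetic import make_fixture

from conftest import random_pairs


# --- P30 / P15 --------------------------------------------------------------

def test_p_within_zero_error_is_100():
    m = np.array([40.0, 75.0, 120.0])
    assert p_within(m, m, 0.30) == 100.0


def test_p_within_boundary_inclusive():
    assert p_within([70.0], [100.0], 0.30) == 100.0
    assert p_within([69.999], [100.0], 0.30) == 0.0


def test_p30_hand_fixture_is_75_percent():
    fx = make_fixture("concordance")
    assert p_within(fx["egfr"], fx["mgfr"], 0.30) == 75.0
    assert p_within(fx["egfr"], fx["mgfr"], 0.15) == 25.0


def test_empty_series_raises():
    with pytest.raises(EmptySeriesError):
        p_within([], [], 0.30)
    with pytest.raises(EmptySeriesError):
        bias_precision([], [])


def test_nonpositive_mgfr_rejected():
    with pytest.raises(DomainError):
        p_within([50.0], [0.0], 0.30)


# --- bias / precision -------------------------------------------------------

def test_constant_shift_bias():
    m = np.array([40.0, 60.0, 90.0, 120.0])
    bias, iqr = bias_precision(m + 5.0, m)
    assert bias == 5.0 and iqr == 0.0


def test_symmetric_differences_zero_bias():
    m = np.array([50.0, 50.0, 50.0])
    bias, _ = bias_precision(m + np.array([-10.0, 0.0, 10.0]), m)
    assert bias == 0.0


def test_iqr_matches_sort_based_oracle():
    diffs = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
    m = np.full(5, 50.0)
    bias, iqr = bias_precision(m + diffs, m)
    assert bias == 3.0
    # linear-interpolation quantiles on the sorted differences
    q1 = np.sort(diffs)[1]  # position 0.25*(5-1) = 1 exactly
    q3 = np.sort(diffs)[3]
    assert iqr == pytest.approx(q3 - q1, abs=1e-12)


def test_bias_equivariance_under_constant_shift(rng):
    e, m = random_pairs(rng, 400)
    b0, i0 = bias_precision(e, m)
    b1, i1 = bias_precision(e + 7.5, m)
    assert b1 == pytest.approx(b0 + 7.5, abs=1e-9)
    assert i1 == pytest.approx(i0, abs=1e-9)


# --- grading ----------------------------------------------------------------

@pytest.mark.parametrize("p30, grade", [
    (91.0, "optimal"), (90.0, "acceptable"), (80.0, "acceptable"),
    (79.999, "unacceptable"),
])
def test_p30_grades(p30, grade):
    assert grade_p30(p30) == grade


@pytest.mark.parametrize("bias, grade", [
    (-7.0, "medium"), (5.0, "small"), (-5.0, "small"), (10.0, "medium"),
    (10.5, "large"), (0.0, "small"),
])
def test_bias_grades(bias, grade):
    assert grade_bias(bias) == grade


# --- banding and contingency ------------------------------------------------

@pytest.mark.parametrize("value, band", [
    (29.999, 0), (30.0, 1), (44.999, 1), (45.0, 2), (75.0, 3),
    (119.999, 4), (120.0, 5), (500.0, 5), (0.0, 0),
])
def test_band_of_left_closed(value, band):
    assert band_of(value) == band


def test_band_of_rejects_negative():
    with pytest.raises(DomainError):
        band_of(-1.0)


def test_contingency_single_band_all_diagonal():
    m = np.full(10, 75.0)
    bt = contingency(m, m)
    assert bt.percent_agreement == 100.0
    assert bt.row_percent[3, 3] == 100.0


def test_contingency_hand_fixture():
    bt = contingency(np.array([35.0, 50.0]), np.array([35.0, 35.0]))
    assert bt.row_percent[1, 1] == 50.0 and bt.row_percent[1, 2] == 50.0
    assert bt.percent_agreement == 50.0
    assert bt.row_counts[1] == 2


def test_contingency_order_invariant(rng):
    e, m = random_pairs(rng, 200)
    perm = rng.permutation(200)
    a, b = contingency(e, m), contingency(e[perm], m[perm])
    assert np.array_equal(a.counts, b.counts)
    assert a.percent_agreement == b.percent_agreement


def test_contingency_invariants_on_random_cohorts(rng):
    """Nonzero rows sum to 100%; agreement equals the count-weighted diagonal."""
    for _ in range(50):
        e, m = random_pairs(rng, int(rng.integers(5, 200)))
        bt = contingency(e, m)
        nz = bt.row_counts > 0
        assert np.allclose(bt.row_percent[nz].sum(axis=1), 100.0, atol=1e-9)
        recon = (bt.row_counts * np.diag(bt.row_percent)).sum() / (100.0 * len(e))
        assert bt.percent_agreement == pytest.approx(100.0 * recon, abs=1e-9)


def test_p15_nested_in_p30_on_random_cohorts(rng):
    for _ in range(50):
        e, m = random_pairs(rng, int(rng.integers(2, 300)))
        assert p_within(e, m, 0.15) <= p_within(e, m, 0.30)


# --- stratification ---------------------------------------------------------

def test_stratify_single_group_equals_overall(rng):
    e, m = random_pairs(rng, 100)
    out = stratify(e, m, np.full(100, "female"))
    assert list(out) == ["female"]
    assert out["female"] == summarize(e, m)


def test_stratify_partitions_n(rng):
    e, m = random_pairs(rng, 150)
    labels = rng.choice(["<20", "20-<25", "25-<30"], 150)
    out = stratify(e, m, labels)
    assert sum(s.n for s in out.values()) == 150


def test_stratify_recovers_constructed_shift():
    m = np.full(40, 80.0)
    labels = np.array(["a"] * 20 + ["b"] * 20)
    e = m + np.where(labels == "a", 12.0, -12.0)
    out = stratify(e, m, labels)
    assert out["a"].bias_median > 0 > out["b"].bias_median


def test_stratify_unknown_key_is_configuration_error():
    with pytest.raises(ConfigurationError):
        stratify([80.0], [80.0], ["oddball"], valid_keys=("female", "male"))


# --- Bland-Altman -----------------------------------------------------------

def test_bland_altman_zero_and_shifted():
    m = np.array([40.0, 80.0, 120.0])
    table, summary = bland_altman(m, m)
    assert np.all(table["difference"] == 0.0)
    table, summary = bland_altman(m + 5.0, m)
    assert np.all(table["difference"] == 5.0)
    assert summary["bias_median"] == 5.0 and summary["precision_iqr"] == 0.0


def test_bland_altman_percentiles_match_sort_oracle(rng):
    e, m = random_pairs(rng, 500)
    _, summary = bland_altman(e, m)
    d = np.sort(e - m)
    assert summary["p2_5"] == pytest.approx(np.percentile(d, 2.5), abs=1e-9)
    assert summary["p97_5"] == pytest.approx(np.percentile(d, 97.5), abs=1e-9)
    assert summary["bias_median"] == pytest.approx(np.median(d), abs=1e-12)


def test_summary_invariants(rng):
    e, m = random_pairs(rng, 250)
    s = summarize(e, m)
    assert 0 <= s.p15 <= s.p30 <= 100
    assert s.precision_iqr >= 0
    assert s.n == 250
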