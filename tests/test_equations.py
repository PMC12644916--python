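import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfrconcord import (
    Anthropometrics, MarkerPanel, deindex_gfr, evaluate, evaluate_all,
    invert_marker, known_equations,
)
from gfrconcord.equations import DEFAULT_SELECTION, _INVERTIBLE
from gfrconcord.errors import ConfigurationError, DomainError, InputError

finite = dict(allow_nan=False, allow_infinity=False)


def panel(age=68.0, sex="male", scr=None, scys=None, weight=None):
    return MarkerPanel(age=age, sex=sex, scr=scr, scys=scys, weight=weight)


# --- knot-point values (both power terms equal one) ------------------------

def test_ckdepi2009_at_knot_is_intercept_times_age_decay():
    assert evaluate("ckdepi2009_cr", panel(age=60, sex="male", scr=0.9)) == \
        pytest.approx(141 * 0.993**60, rel=1e-12)
    assert evaluate("ckdepi2009_cr", panel(age=60, sex="female", scr=0.7)) == \
        pytest.approx(141 * 0.993**60 * 1.018, rel=1e-12)


def test_ckdepi2012_cys_at_knot():
    assert evaluate("ckdepi2012_cys", panel(age=50, sex="male", scys=0.8)) == \
        pytest.approx(133 * 0.996**50, rel=1e-12)
    assert evaluate("ckdepi2012_cys", panel(age=50, sex="female", scys=0.8)) == \
        pytest.approx(133 * 0.996**50 * 0.932, rel=1e-12)


def test_ekfc_cr_at_knot_below_age_decay_is_constant():
    assert evaluate("ekfc2021_cr", panel(age=30, sex="male", scr=0.90)) == \
        pytest.approx(107.3, rel=1e-12)


def test_ekfc_cys_at_knot_with_age_decay():
    assert evaluate("ekfc2023_cys", panel(age=45, sex="male", scys=0.83)) == \
        pytest.approx(107.3 * 0.990**5, rel=1e-12)


# --- derived closed-form oracle values -------------------------------------

def test_ckdepi2009_female_above_knot_matches_direct_evaluation():
    # female, age 60, Scr 1.2 mg/dL > kappa: steep branch only
    expected = 141 * (1.2 / 0.7) ** (-1.209) * 0.993**60 * 1.018
    assert evaluate("ckdepi2009_cr", panel(age=60, sex="female", scr=1.2)) == \
        pytest.approx(expected, rel=1e-12)


def test_ekfc_cr_female_above_knot_matches_direct_evaluation():
    expected = 107.3 / (1.1 / 0.7) ** 1.132 * 0.990 ** (70 - 40)
    assert evaluate("ekfc2021_cr", panel(age=70, sex="female", scr=1.1)) == \
        pytest.approx(expected, rel=1e-12)


def test_cockcroft_gault_worked_examples():
    # weight 72 kg cancels the 72 denominator
    assert evaluate("cockcroft_gault", panel(age=68, sex="male", scr=1.0, weight=72)) == \
        pytest.approx(72.0, rel=1e-12)
    male = evaluate("cockcroft_gault", panel(age=50, sex="male", scr=1.1, weight=80))
    female = evaluate("cockcroft_gault", panel(age=50, sex="female", scr=1.1, weight=80))
    assert female / male == pytest.approx(0.85, rel=1e-12)
    assert evaluate("cockcroft_gault", panel(age=40, sex="male", scr=1.25, weight=80)) == \
        pytest.approx((140 - 40) * 80 / (72 * 1.25), rel=1e-12)


def test_ekfc_combined_is_mean_of_components():
    p = panel(age=68, sex="female", scr=0.9, scys=1.2)
    cr = evaluate("ekfc2021_cr", p)
    cys = evaluate("ekfc2023_cys", p)
    assert evaluate("ekfc2023_crcys", p) == pytest.approx((cr + cys) / 2, rel=1e-14)
    # both markers at their knots, age below decay threshold -> exactly 107.3
    assert evaluate("ekfc2023_crcys", panel(age=30, sex="male", scr=0.90, scys=0.83)) == \
        pytest.approx(107.3, rel=1e-12)


# --- structural properties --------------------------------------------------

# Marker knot locations per equation at age 68: CKD-EPI kappa, EKFC Q
# (cystatin Q at age 68 is 0.83 + 0.005 * 18 = 0.92 mg/L).
KNOTS = {
    "ckdepi2009_cr": {"scr": {"female": 0.7, "male": 0.9}},
    "ckdepi2021_cr": {"scr": {"female": 0.7, "male": 0.9}},
    "ckdepi2012_cys": {"scys": {"female": 0.8, "male": 0.8}},
    "ckdepi2012_crcys": {"scr": {"female": 0.7, "male": 0.9},
                         "scys": {"female": 0.8, "male": 0.8}},
    "ekfc2021_cr": {"scr": {"female": 0.7, "male": 0.9}},
    "ekfc2023_cys": {"scys": {"female": 0.92, "male": 0.92}},
    "ekfc2023_crcys": {"scr": {"female": 0.7, "male": 0.9},
                       "scys": {"female": 0.92, "male": 0.92}},
}


@pytest.mark.parametrize("eq_id", list(KNOTS))
def test_knot_continuity_and_monotone_decrease(eq_id):
    """Every piecewise equation is continuous at its knot(s) and strictly
    decreasing in each marker it uses."""
    eps = 1e-9
    for sex in ("female", "male"):
        for marker, by_sex in KNOTS[eq_id].items():
            knot = by_sex[sex]
            other = {"scr": 1.0, "scys": 1.0}
            other.pop(marker)
            lo = evaluate(eq_id, panel(sex=sex, **{marker: knot - eps, **other}))
            hi = evaluate(eq_id, panel(sex=sex, **{marker: knot + eps, **other}))
            assert lo == pytest.approx(hi, rel=1e-6)
            assert lo >= hi  # decreasing through the knot
    # strict monotone decrease over a coarse grid spanning both branches
    grid = np.linspace(0.3, 4.0, 25)
    for sex in ("female", "male"):
        for marker in KNOTS[eq_id]:
            vals = [evaluate(eq_id, panel(sex=sex, **{marker: m,
                    ("scys" if marker == "scr" else "scr"): 1.0}))
                    for m in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))


@given(scr=st.floats(0.3, 4.0, **finite), scys=st.floats(0.3, 4.0, **finite),
       age=st.floats(18, 90, **finite))
@settings(max_examples=60, derandomize=True)
def test_age_nonincreasing_and_sex_ordering(scr, scys, age):
    for eq_id in ("ckdepi2009_cr", "ckdepi2012_cys", "ekfc2021_cr", "ekfc2023_crcys"):
        young = evaluate(eq_id, panel(age=age, sex="male", scr=scr, scys=scys))
        old = evaluate(eq_id, panel(age=age + 5, sex="male", scr=scr, scys=scys))
        assert old <= young + 1e-12
        assert young > 0


def test_evaluate_all_cardinality_and_internal_consistency():
    p = panel(age=68, sex="male", scr=1.0, scys=1.1, weight=80)
    anthro = Anthropometrics(178.0, 80.0)
    results = evaluate_all(p, anthro, DEFAULT_SELECTION)
    assert len(results) == 7
    for r in results:
        if r.equation_id == "cockcroft_gault":
            assert r.egfr_indexed is None and r.egfr_nonindexed > 0
        else:
            assert r.egfr_nonindexed == pytest.approx(
                deindex_gfr(r.egfr_indexed, anthro.bsa), rel=1e-14)


def test_evaluate_all_order_independent():
    p = panel(age=68, sex="female", scr=0.9, scys=1.0, weight=70)
    a = Anthropometrics(165.0, 70.0)
    fwd = {r.equation_id: r for r in evaluate_all(p, a, DEFAULT_SELECTION)}
    rev = {r.equation_id: r for r in evaluate_all(p, a, DEFAULT_SELECTION[::-1])}
    assert fwd == rev


def test_unknown_equation_id_lists_known_ids():
    with pytest.raises(ConfigurationError, match="ckdepi2009_cr"):
        evaluate("mdrd", panel(scr=1.0))


def test_missing_marker_raises_input_error_naming_it():
    with pytest.raises(InputError, match="cys"):
        evaluate("ckdepi2012_cys", panel(scr=1.0))
    with pytest.raises(InputError, match="weight"):
        evaluate("cockcroft_gault", panel(scr=1.0))


def test_panel_validation():
    with pytest.raises(InputError):
        MarkerPanel(age=50, sex="male")  # no marker at all
    with pytest.raises(DomainError):
        MarkerPanel(age=17, sex="male", scr=1.0)
    with pytest.raises(DomainError):
        MarkerPanel(age=50, sex="male", scr=-1.0)


# --- marker inversion -------------------------------------------------------

def _bisect(eq_id, target, age, sex, lo=1e-4, hi=50.0, iters=200):
    """Independent bisection oracle on the (decreasing) marker -> eGFR map."""
    def f(m):
        kwargs = {"scr": m} if eq_id.endswith("_cr") else {"scys": m}
        return evaluate(eq_id, MarkerPanel(age=age, sex=sex, **kwargs)) - target
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize("eq_id", _INVERTIBLE)
def test_invert_round_trip_and_bisection_agreement(eq_id, rng):
    for _ in range(30):
        age = rng.uniform(18, 90)
        sex = "female" if rng.random() < 0.5 else "male"
        g = rng.uniform(10, 140)
        m = invert_marker(eq_id, g, age, sex)
        kwargs = {"scr": m} if eq_id.endswith("_cr") else {"scys": m}
        achieved = evaluate(eq_id, MarkerPanel(age=age, sex=sex, **kwargs))
        assert achieved == pytest.approx(g, rel=1e-10)
        assert m == pytest.approx(_bisect(eq_id, g, age, sex), rel=1e-8)


def test_invert_knot_image_is_exact():
    # the eGFR value attained at the knot inverts back to the knot marker
    target = 141 * 0.993**68
    assert invert_marker("ckdepi2009_cr", target, 68, "male") == pytest.approx(0.9, rel=1e-12)
    assert invert_marker("ekfc2021_cr", 107.3, 30, "male") == pytest.approx(0.9, rel=1e-12)


def test_invert_rejects_bad_targets_and_equations():
    with pytest.raises(DomainError):
        invert_marker("ckdepi2009_cr", -5.0, 60, "male")
    with pytest.raises(ConfigurationError):
        invert_marker("ckdepi2012_crcys", 60.0, 60, "male")
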