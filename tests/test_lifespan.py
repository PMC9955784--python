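"""Entropic-age ledger, disease adjustment, lifespan projection, scenarios."""

import pytest
from hypothesis import given, strategies as st

from entroage import (
    EntropyLedger,
    Segment,
    SurvivalAdjustment,
    accumulate,
    autophagy_adjusted_segment,
    constant_rate_lifespan,
    disease_adjusted_rate,
    project_lifespan,
    run_scenario,
    scenario_compare,
)
from entroage.lifespan import ScenarioError

LIMIT = 11404.0


def _single(age, acc, rate, limit=LIMIT):
    return EntropyLedger(age, acc, [Segment(rate)], limit=limit)


# ------------------------------------------------------------- accumulation

@pytest.mark.parametrize(
    "rate, years, expected",
    [(119.9, 40, 4796.0), (102.4, 25, 2560.0), (55.0, 0, 0.0)],
)
def test_accumulate(rate, years, expected):
    assert accumulate(rate, years) == pytest.approx(expected)


# -------------------------------------------------------- disease adjustment

@pytest.mark.parametrize(
    "survival, expected",
    [(0.95, 126.2), (0.80, 149.9), (0.44, 272.5)],
)
def test_childpugh_survival_adjusted_rates(survival, expected):
    adjusted = disease_adjusted_rate(119.9, SurvivalAdjustment(survival))
    assert adjusted == pytest.approx(expected, abs=0.1)


def test_survival_of_one_is_identity():
    assert disease_adjusted_rate(87.3, SurvivalAdjustment(1.0)) == 87.3
    with pytest.raises(ScenarioError):
        SurvivalAdjustment(0.0)


def test_autophagy_reduction():
    assert autophagy_adjusted_segment(100.0, 0.10) == pytest.approx(90.0)
    assert autophagy_adjusted_segment(100.0, 0.0) == 100.0
    # the published weight-loss rate pair 121 -> 91 implies ~25% reduction
    assert autophagy_adjusted_segment(121.0, 0.25) == pytest.approx(91.0, abs=0.5)
    with pytest.raises(ValueError):
        autophagy_adjusted_segment(100.0, 1.0)


# --------------------------------------------------------------- projection

@pytest.mark.parametrize(
    "rate, expected_years",
    [(126.2, 92), (149.9, 84), (272.5, 64)],   # no diet change
)
def test_childpugh_no_change_lifespans(rate, expected_years):
    est = project_lifespan(_single(40, 4796, rate))
    assert abs(est.rounded - expected_years) <= 1


@pytest.mark.parametrize(
    "rate, expected_years",
    [(76.4, 127), (87.2, 116), (98.8, 107)],   # post-diet-change rates
)
def test_childpugh_diet_change_lifespans(rate, expected_years):
    est = project_lifespan(_single(40, 4796, rate))
    assert abs(est.rounded - expected_years) <= 1


@pytest.mark.parametrize("rate, expected_years", [(135.0, 100), (121.0, 106)])
def test_if_50_year_old_lifespans(rate, expected_years):
    est = project_lifespan(_single(50, 4651, rate))
    assert abs(est.rounded - expected_years) <= 1


def test_budget_already_reached():
    est = project_lifespan(_single(40, LIMIT, 100.0))
    assert est.expected_lifespan == 40
    assert est.remaining_years == 0


def test_multi_segment_walk():
    # ten years at 200 then open-ended at 100: 4796+2000 -> remaining 4608
    ledger = EntropyLedger(40, 4796, [Segment(200.0, duration=10), Segment(100.0)])
    est = project_lifespan(ledger)
    assert est.expected_lifespan == pytest.approx(50 + (LIMIT - 6796) / 100.0)


def test_constant_rate_closed_form():
    assert round(constant_rate_lifespan(0.46e-5)) == 79
    assert constant_rate_lifespan(0.92e-5) == pytest.approx(
        constant_rate_lifespan(0.46e-5) / 2
    )
    one_year_rate = LIMIT / (365 * 86400) * 1.0  # kW/(kg K) exhausting in 1 yr
    assert constant_rate_lifespan(one_year_rate) == pytest.approx(1.0)


# ----------------------------------------------------- properties/invariants

@given(
    rate=st.floats(20, 400), acc=st.floats(0, 11000), age=st.floats(0, 90),
    bump=st.floats(1, 100),
)
def test_lifespan_monotone_decreasing_in_rate(rate, acc, age, bump):
    base = project_lifespan(_single(age, acc, rate)).expected_lifespan
    faster = project_lifespan(_single(age, acc, rate + bump)).expected_lifespan
    if acc < LIMIT:
        assert faster < base
    else:
        assert faster == base == age


@given(rate=st.floats(20, 400), acc=st.floats(0, 11403), age=st.floats(0, 90))
def test_accumulate_project_round_trip(rate, acc, age):
    est = project_lifespan(_single(age, acc, rate))
    total = acc + accumulate(rate, est.expected_lifespan - age)
    assert total == pytest.approx(LIMIT, rel=1e-12)


def test_closed_form_consistency():
    est = project_lifespan(_single(40, 4796, 126.2))
    assert est.expected_lifespan == pytest.approx(40 + (LIMIT - 4796) / 126.2)


# ------------------------------------------------------------------ scenario

def test_scenario_compare_matches_published_gains():
    base_c = _single(40, 4796, 272.5)
    alt_c = _single(40, 4796, 98.8)
    gained, rounded = scenario_compare(base_c, alt_c)
    assert rounded == 43
    _, rounded_b = scenario_compare(_single(40, 4796, 149.9), _single(40, 4796, 87.2))
    assert rounded_b == 32


def test_scenario_compare_identity_and_mismatch():
    ledger = _single(40, 4796, 119.9)
    assert scenario_compare(ledger, ledger) == (0.0, 0)
    with pytest.raises(ScenarioError):
        scenario_compare(ledger, _single(41, 4796, 119.9))


def test_ledger_validation():
    with pytest.raises(ScenarioError):
        EntropyLedger(40, LIMIT + 1, [Segment(100.0)])
    with pytest.raises(ScenarioError):
        EntropyLedger(40, 100, [Segment(100.0, duration=5)])  # no open end
    with pytest.raises(ScenarioError):
        Segment(rate=-5.0)


def test_run_scenario_childpugh_c():
    report = run_scenario(
        {
            "name": "childpugh_C",
            "onset_age": 40,
            "pre_onset": {"rate": 119.9},
            "baseline": {"rate": 119.9, "survival_fraction": 0.44},
            "alternative": {"rate": 98.8},
        }
    )
    assert report["accumulated_kJ_per_kgK"] == pytest.approx(4796.0)
    assert report["baseline"]["annual_rate_kJ_per_kgK_year"] == pytest.approx(272.5, abs=0.1)
    assert report["baseline"]["expected_lifespan_rounded"] == 64
    assert report["alternative"]["expected_lifespan_rounded"] == 107
    assert report["years_gained_rounded"] == 43


def test_run_scenario_computes_rates_from_diets():
    report = run_scenario(
        {
            "onset_age": 40,
            "subject": "nafld_obese",
            "pre_onset": {"diet": "healthy_obese"},
            "baseline": {"diet": "healthy_obese"},
        }
    )
    rate = report["baseline"]["annual_rate_kJ_per_kgK_year"]
    assert rate == pytest.approx(119.9, rel=0.05)
    # healthy obese continuing the same diet lives into the mid-nineties
    assert 90 <= report["baseline"]["expected_lifespan_rounded"] <= 100


def test_run_scenario_rejects_subject_older_than_onset():
    with pytest.raises(ScenarioError):
        run_scenario(
            {
                "onset_age": 30,
                "subject": {"weight_kg": 80, "height_cm": 170, "age_years": 40},
                "pre_onset": {"rate": 100.0},
                "baseline": {"rate": 100.0},
            }
        )
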