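"""Expected-value arithmetic: worked examples, break-even roots, invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cultev import (
    CultivationProbability,
    EmptyProjectError,
    IsolateCategory,
    ProjectScenario,
    UnboundedBreakEvenError,
    ValidationError,
    breakeven_cost,
    breakeven_project_cost,
    breakeven_value,
    classify_ev,
    ev_project,
    ev_single,
    largest_positive_thousand,
    round_to_hundred,
)

values = st.floats(0, 1e8, allow_nan=False, allow_infinity=False)
probs = st.floats(0, 1, allow_nan=False, allow_infinity=False)
costs = st.floats(0, 1e7, allow_nan=False, allow_infinity=False)


class TestEvSingle:
    @pytest.mark.parametrize(
        "i, cp, e, expected",
        [
            (500_000, 0.0146, 0.0, 7300.0),  # zero cost: EV = i*cP
            (10_000_000, 0.001, 100_000, -89_900.0),  # $10M at 0.1%, e = $100k
            (0, 0.5, 100, -50.0),
        ],
    )
    def test_worked_examples(self, i, cp, e, expected):
        result = ev_single(i, cp, e)
        assert result.value == pytest.approx(expected)
        assert result.value == pytest.approx(result.reward_term - result.cost_term)

    def test_zero_at_breakeven_cost(self):
        e_star = breakeven_cost(500_000, 0.0146)
        assert abs(ev_single(500_000, 0.0146, e_star).value) < 1.0

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0])
    def test_rejects_nonfinite_or_negative(self, bad):
        with pytest.raises(ValidationError):
            ev_single(bad, 0.5, 100)
        with pytest.raises(ValidationError):
            ev_single(100, 0.5, bad)

    @settings(derandomize=True, max_examples=200)
    @given(i=values, cp=probs, e1=costs, e2=costs)
    def test_decreasing_in_cost_with_slope(self, i, cp, e1, e2):
        """EV is linear in e with slope -(1-cP)."""
        v1 = ev_single(i, cp, e1).value
        v2 = ev_single(i, cp, e2).value
        assert v1 - v2 == pytest.approx((e2 - e1) * (1 - cp), abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(i1=values, i2=values, cp=st.floats(1e-6, 1), e=costs)
    def test_increasing_in_value(self, i1, i2, cp, e):
        lo, hi = sorted([i1, i2])
        assert ev_single(lo, cp, e).value <= ev_single(hi, cp, e).value + 1e-9


class TestBreakeven:
    def test_iiia_single_breakeven(self):
        e_star = breakeven_cost(500_000, 0.0146)
        assert e_star == pytest.approx(7408.1591231987, rel=1e-9)
        assert round_to_hundred(e_star) == 7400

    @pytest.mark.parametrize(
        "i, cp, expected",
        [(50_000, 0.282, 19637.883008356544), (100, 0.0, 0.0)],
    )
    def test_formula(self, i, cp, expected):
        assert breakeven_cost(i, cp) == pytest.approx(expected, rel=1e-9)

    def test_certain_cultivation_has_no_breakeven(self):
        with pytest.raises(UnboundedBreakEvenError):
            breakeven_cost(100, 1.0)

    @pytest.mark.parametrize(
        "e, cp, expected",
        [(7408.1591231987, 0.0146, 500_000), (0, 0.5, 0), (100_000, 0.001, 99_900_000)],
    )
    def test_breakeven_value(self, e, cp, expected):
        assert breakeven_value(e, cp) == pytest.approx(expected, rel=1e-9)

    def test_breakeven_value_zero_probability(self):
        with pytest.raises(UnboundedBreakEvenError):
            breakeven_value(100, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(i=st.floats(1, 1e8), cp=st.floats(1e-6, 1 - 1e-9))
    def test_root_property(self, i, cp):
        """EV evaluated at its break-even cost is zero (relative 1e-9)."""
        e_star = breakeven_cost(i, cp)
        scale = max(1.0, i * cp)
        assert abs(ev_single(i, cp, e_star).value) <= 1e-9 * scale


class TestEvProject:
    def test_two_isolate_portfolio(self, two_isolate_project):
        at_25k = ev_project(ProjectScenario(two_isolate_project, 25_000))
        assert at_25k.value == pytest.approx(107.5, abs=1e-6)
        assert at_25k.sign == "positive"
        at_26k = ev_project(ProjectScenario(two_isolate_project, 26_000))
        assert at_26k.value == pytest.approx(-744.2, abs=1e-6)
        assert at_26k.sign == "non-positive"

    def test_single_isolate_reduces_to_ev_single(self, iiia_category):
        proj = ev_project(ProjectScenario([iiia_category], 7400))
        single = ev_single(iiia_category.value, iiia_category.cp, 7400)
        assert proj.value == single.value

    def test_empty_project_is_an_error_not_zero(self):
        with pytest.raises(EmptyProjectError):
            ev_project(ProjectScenario([], 1000))
        with pytest.raises(EmptyProjectError):
            ev_project(ProjectScenario([IsolateCategory("z", 100, 0.5, 0)], 1000))

    def test_per_category_sums_to_total(self, two_isolate_project):
        result = ev_project(ProjectScenario(two_isolate_project, 25_000))
        assert sum(v for _, v in result.per_category) == pytest.approx(result.value)

    @settings(derandomize=True, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(values, probs, st.integers(0, 5)), min_size=1, max_size=6
        ).filter(lambda d: sum(c for _, _, c in d) >= 1),
        e=costs,
    )
    def test_matches_bruteforce_per_isolate_expansion(self, data, e):
        """Category-aggregated project EV equals the per-isolate brute force sum."""
        cats = [IsolateCategory(f"c{k}", i, p, n) for k, (i, p, n) in enumerate(data)]
        x = sum(c.count for c in cats)
        brute = sum(
            c.value * c.cp.value - (e / x) * (1 - c.cp.value)
            for c in cats
            for _ in range(c.count)
        )
        result = ev_project(ProjectScenario(cats, e)).value
        assert result == pytest.approx(brute, rel=1e-9, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(values, probs, st.integers(0, 5)), min_size=1, max_size=6
        ).filter(lambda d: sum(c for _, _, c in d) >= 1),
        e=costs,
    )
    def test_reward_bounds(self, data, e):
        """Sum(i*cP) - e <= project EV <= Sum(i*cP)."""
        cats = [IsolateCategory(f"c{k}", i, p, n) for k, (i, p, n) in enumerate(data)]
        result = ev_project(ProjectScenario(cats, e))
        reward = result.reward_term
        assert reward - e - 1e-6 <= result.value <= reward + 1e-6


class TestBreakevenProject:
    def test_two_isolate_portfolio_breakeven(self, two_isolate_project):
        e_star = breakeven_project_cost(two_isolate_project)
        assert e_star == pytest.approx(25126.218151931433, rel=1e-9)
        assert largest_positive_thousand(two_isolate_project) == 25_000

    def test_single_category_reduces_to_single_breakeven(self, iiia_category):
        assert breakeven_project_cost([iiia_category]) == pytest.approx(
            breakeven_cost(iiia_category.value, iiia_category.cp), rel=1e-12
        )

    def test_symmetric_two_isolate_hand_case(self):
        assert breakeven_project_cost([IsolateCategory("s", 100, 0.5, 2)]) == pytest.approx(200.0)

    def test_all_certain_is_unbounded(self):
        with pytest.raises(UnboundedBreakEvenError):
            breakeven_project_cost([IsolateCategory("c", 100, 1.0, 2)])

    @settings(derandomize=True, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(st.floats(1, 1e7), st.floats(0, 0.999), st.integers(1, 5)),
            min_size=1,
            max_size=5,
        )
    )
    def test_project_ev_zero_at_breakeven(self, data):
        cats = [IsolateCategory(f"c{k}", i, p, n) for k, (i, p, n) in enumerate(data)]
        e_star = breakeven_project_cost(cats)
        result = ev_project(ProjectScenario(cats, e_star))
        scale = max(1.0, result.reward_term)
        assert abs(result.value) <= 1e-9 * scale


def test_sign_classification_is_strict_at_zero():
    assert classify_ev(1e-12) == "positive"
    assert classify_ev(0.0) == "non-positive"
    assert classify_ev(-5.0) == "non-positive"


def test_round_to_hundred():
    assert round_to_hundred(7408.16) == 7400
    assert round_to_hundred(396.34) == 400
    assert round_to_hundred(350.0) == 400
    assert round_to_hundred(0.0) == 0


def test_cultivation_probability_bounds():
    with pytest.raises(ValidationError):
        CultivationProbability(1.5)
    with pytest.raises(ValidationError):
        CultivationProbability(-0.1)
    with pytest.raises(ValidationError):
        CultivationProbability(math.nan)
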