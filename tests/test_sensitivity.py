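"""Unit tests for one-way sensitivity, tornado ordering and break-even."""

import pytest

from wellcost import (
    NoThresholdError,
    UnknownParameterError,
    break_even,
    bundled_fixtures,
    evaluate,
    one_way,
    tornado,
)
from wellcost.sensitivity import (
    PARAMETERS,
    affine_coefficients,
    default_ranges,
    parameter_value,
    substitute,
)

from conftest import bisect_break_even


@pytest.fixture(scope="module")
def fixtures():
    return bundled_fixtures()


class TestOneWay:
    def test_degenerate_interval_equals_base(self, fixtures):
        s = fixtures["base_case"]
        base = evaluate(s)
        lo, hi = one_way(s, "cost_per_person", 100, 100)
        assert lo == base
        assert hi == base

    def test_intervention_cost_range_free_to_661(self, fixtures):
        # oracle: evaluate() on hand-substituted scenarios
        s = fixtures["base_case"]
        lo, hi = one_way(s, "cost_per_person", 0, 661)
        assert lo.total_incremental_cost == pytest.approx(-222_963.20)
        assert hi.total_incremental_cost == pytest.approx(-189_913.20)
        for bound, result in [(0, lo), (661, hi)]:
            assert result == evaluate(substitute(s, "cost_per_person", bound))

    def test_turnover_reduction_zero_to_two_pp(self, fixtures):
        lo, hi = one_way(fixtures["scenario_4"], "turnover_reduction_pp", 0, 2)
        assert lo.total_incremental_cost == pytest.approx(2080)
        assert hi.total_incremental_cost == pytest.approx(-5215.20)

    def test_low_above_high_rejected(self, fixtures):
        with pytest.raises(ValueError):
            one_way(fixtures["base_case"], "cost_per_person", 10, 5)

    def test_unmodelled_parameter_rejected(self, fixtures):
        with pytest.raises(UnknownParameterError, match="turnover_per_case"):
            one_way(fixtures["scenario_2"], "turnover_per_case", 0, 1)

    def test_monotone_directions(self, fixtures):
        s = fixtures["base_case"]
        lo, hi = one_way(s, "cost_per_person", 50, 150)
        assert lo.total_incremental_cost <= hi.total_incremental_cost
        lo, hi = one_way(s, "absenteeism_days_avoided", 2, 6)
        assert lo.total_incremental_cost >= hi.total_incremental_cost


class TestTornado:
    def test_single_parameter_matches_one_way(self, fixtures):
        s = fixtures["base_case"]
        [entry] = tornado(s, [("cost_per_person", 0, 661)])
        lo, hi = one_way(s, "cost_per_person", 0, 661)
        assert entry.total_at_low == lo.total_incremental_cost
        assert entry.total_at_high == hi.total_incremental_cost
        assert entry.span == pytest.approx(
            abs(hi.total_incremental_cost - lo.total_incremental_cost)
        )

    def test_widening_a_range_cannot_drop_its_rank(self, fixtures):
        s = fixtures["base_case"]
        narrow = [("absenteeism_per_day", 150, 230), ("cost_per_person", 0, 661)]
        wide = [("absenteeism_per_day", 0, 600), ("cost_per_person", 0, 661)]
        before = tornado(s, narrow)
        after = tornado(s, wide)
        span_before = next(e.span for e in before if e.parameter == "absenteeism_per_day")
        span_after = next(e.span for e in after if e.parameter == "absenteeism_per_day")
        assert span_after >= span_before
        rank = lambda entries: [e.parameter for e in entries].index("absenteeism_per_day")
        assert rank(after) <= rank(before)

    def test_all_degenerate_ranges_fall_back_to_canonical_order(self, fixtures):
        s = fixtures["base_case"]
        present = [p for p in PARAMETERS if p not in
                   ("turnover_per_case", "turnover_reduction_pp")]
        ranges = [(p, parameter_value(s, p), parameter_value(s, p)) for p in present]
        entries = tornado(s, list(reversed(ranges)))
        assert all(e.span == 0 for e in entries)
        assert [e.parameter for e in entries] == present

    def test_empty_range_list_is_empty_result(self, fixtures):
        assert tornado(fixtures["base_case"], []) == []

    def test_base_total_lies_between_bounds(self, fixtures):
        s = fixtures["base_case"]
        base = evaluate(s).total_incremental_cost
        for entry in tornado(s, default_ranges(s)):
            lo = min(entry.total_at_low, entry.total_at_high)
            hi = max(entry.total_at_low, entry.total_at_high)
            assert lo - 1e-9 <= base <= hi + 1e-9

    def test_default_ranges_skip_unmodelled_and_respect_overrides(self, fixtures):
        s = fixtures["scenario_4"]
        ranges = dict((p, (lo, hi)) for p, lo, hi in
                      default_ranges(s, overrides={"cost_per_person": (0, 661)}))
        assert "absenteeism_per_day" not in ranges
        assert ranges["cost_per_person"] == (0, 661)
        assert ranges["turnover_reduction_pp"] == (1.0, 3.0)


class TestBreakEven:
    def test_base_case_intervention_cost_threshold(self, fixtures):
        s = fixtures["base_case"]
        threshold = break_even(s, "cost_per_person")
        # per-head benefit: 4.3 x 189.76 + 9.6 x 379.51
        assert threshold == pytest.approx(4.3 * 189.76 + 9.6 * 379.51)
        assert threshold == pytest.approx(bisect_break_even(s, "cost_per_person"), rel=1e-9)

    def test_turnover_threshold_small_company(self, fixtures):
        s = fixtures["scenario_4"]
        threshold = break_even(s, "turnover_reduction_pp")
        assert threshold == pytest.approx(2080 / (40 * 9119) * 100)
        assert threshold == pytest.approx(
            bisect_break_even(s, "turnover_reduction_pp"), rel=1e-9
        )

    def test_threshold_zeroes_the_total(self, fixtures):
        s = fixtures["base_case"]
        base = abs(evaluate(s).total_incremental_cost)
        # parameters whose threshold stays inside the valid domain (unit
        # costs would need to go negative to zero this strongly-saving case)
        for parameter in ("cost_per_person", "absenteeism_days_avoided",
                          "presenteeism_days_avoided", "fixed_cost"):
            v = break_even(s, parameter)
            total = evaluate(substitute(s, parameter, v)).total_incremental_cost
            assert abs(total) <= 1e-6 * max(1.0, base)

    def test_base_total_already_zero_returns_base_value(self):
        from wellcost import EffectSizes, InterventionSpec, Scenario, UnitCosts

        # intervention 10 x 100 exactly offset by 10 x 1 day x 100/day
        s = Scenario(
            name="knife_edge",
            intervention=InterventionSpec(n_participants=10, cost_per_person=100),
            unit_costs=UnitCosts(absenteeism_per_day=100),
            effects=EffectSizes(absenteeism_days_avoided=1),
        )
        assert evaluate(s).total_incremental_cost == 0
        assert break_even(s, "cost_per_person") == 100
        assert break_even(s, "absenteeism_days_avoided") == 1

    def test_zero_coefficient_raises(self, fixtures):
        # base case has a turnover unit cost but no turnover effect
        with pytest.raises(NoThresholdError):
            break_even(fixtures["base_case"], "turnover_per_case")

    def test_headcount_with_no_fixed_cost_never_crosses_zero(self, fixtures):
        with pytest.raises(NoThresholdError):
            break_even(fixtures["scenario_4"], "n_participants")

    def test_affine_coefficients_reproduce_evaluate(self, fixtures):
        s = fixtures["scenario_3"]
        for parameter in ("n_participants", "cost_per_person",
                          "turnover_reduction_pp", "absenteeism_per_day"):
            slope, intercept = affine_coefficients(s, parameter)
            for v in (1.0, 7.5, 42.0):
                expected = evaluate(substitute(s, parameter, v)).total_incremental_cost
                assert slope * v + intercept == pytest.approx(expected, rel=1e-12, abs=1e-6)
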