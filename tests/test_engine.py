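"""Prevalence sweeps, crossing-point location and one-way sensitivity analysis."""

import math

import numpy as np
import pytest

from cadcea import (
    ConfigurationError,
    SensitivityScenario,
    TestPerformance,
    ce_curve,
    default_grid,
    evaluate_strategies,
    find_ce_crossing,
    find_cost_crossing,
    fit_link,
    LinkPoint,
    one_way_sensitivity,
    strategy1_expected_cost,
    strategy2_expected_cost,
)


def brute_force_crossing(delta, lo=0.01, hi=1.0, step=1e-4):
    """Independent oracle: argmin |delta| restricted to sign-change neighbourhoods."""
    grid = np.arange(lo, hi + step / 2, step)
    vals = np.array([delta(p) for p in grid])
    sign = np.sign(vals)
    changes = np.where(sign[:-1] * sign[1:] < 0)[0]
    if changes.size == 0:
        return None
    i = changes[0]
    return grid[i] if abs(vals[i]) < abs(vals[i + 1]) else grid[i + 1]


class TestCeCurve:
    def test_default_grid_and_columns(self, perf, costs, link):
        table = ce_curve(perf, costs, link)
        assert list(table.columns) == ["p_isch", "eff1", "eff2", "cost1", "cost2", "cer1", "cer2"]
        assert len(table) == 91  # 10%..100% by 1%
        assert table["p_isch"].iloc[0] == pytest.approx(0.10)

    def test_cer2_hyperbolic_decrease(self, perf, costs, link):
        # with constant strategy-2 numerator cer2*p is constant; here f_ffr makes
        # the numerator increase in p, so cer2 still decreases
        table = ce_curve(perf, costs, link)
        assert np.all(np.diff(table["cer2"]) < 0)
        c = costs.replace(f_ffr=0.0)
        t = ce_curve(perf, c, link)
        np.testing.assert_allclose(t["cer2"] * t["p_isch"], t["cost2"].iloc[0], rtol=1e-12)

    def test_single_point_grid(self, perf, costs, link):
        assert len(ce_curve(perf, costs, link, grid=[0.5])) == 1

    def test_zero_cost_degenerate(self, perf, link, costs):
        c = costs.replace(f_cmr=0.0, f_cxa_outpatient=0.0, f_cxa_inpatient=0.0,
                          f_ffr=0.0, c_complication=0.0)
        table = ce_curve(perf, c, link)
        assert (table[["cost1", "cost2", "cer1", "cer2"]] == 0).all().all()

    def test_empty_grid_rejected(self, perf, costs, link):
        with pytest.raises(ConfigurationError):
            ce_curve(perf, costs, link, grid=[])

    def test_undefined_ratio_rows_flagged_nan(self, perf, costs, link):
        table = ce_curve(perf, costs, link, grid=[0.0, 0.5])
        assert math.isnan(table["cer1"].iloc[0]) and not math.isnan(table["cer1"].iloc[1])


class TestCeCrossing:
    def test_unique_crossing_located_and_consistent(self, perf, costs, link):
        result = find_ce_crossing(perf, costs, link)
        assert result.status == "found"
        s1, s2 = evaluate_strategies(result.p_star, perf, costs, link)
        assert s1.ce_ratio == pytest.approx(s2.ce_ratio, rel=1e-6)
        assert result.ce_at_crossing == pytest.approx(s2.ce_ratio, rel=1e-9)
        # oracle: dense-grid brute force at step 1e-4
        def delta(p):
            a, b = evaluate_strategies(p, perf, costs, link)
            return a.ce_ratio - b.ce_ratio
        assert result.p_star == pytest.approx(brute_force_crossing(delta), abs=2e-4)

    def test_free_cmr_makes_strategy1_dominant_everywhere(self, perf, costs, link):
        assert find_ce_crossing(perf, costs.replace(f_cmr=0.0), link).status == "none_in_domain"

    def test_identical_arms_degenerate_equal(self, costs, link):
        # ndx=1 sends everyone through strategy 2; with a free CMR the arms coincide
        perf = TestPerformance(ndx=1.0)
        result = find_ce_crossing(perf, costs.replace(f_cmr=0.0), link)
        assert result.status == "degenerate_equal"


class TestCostCrossing:
    def test_crossing_matches_brute_force(self, perf, costs, link):
        result = find_cost_crossing(perf, costs, link)
        assert result.status == "found"
        def delta(p):
            return strategy1_expected_cost(p, perf, costs, link) - strategy2_expected_cost(
                p, perf, costs, link
            )
        assert result.p_star == pytest.approx(brute_force_crossing(delta, lo=0.0), abs=2e-4)
        assert result.ce_at_crossing == pytest.approx(
            strategy2_expected_cost(result.p_star, perf, costs, link), rel=1e-9
        )

    def test_expensive_cmr_never_cheaper(self, perf, costs, link):
        c = costs.replace(f_cmr=costs.f_cxa_outpatient + costs.f_ffr + 1.0)
        p = TestPerformance(r_f=0.0)
        assert find_cost_crossing(p, c, link).status == "none_in_domain"

    def test_inpatient_setting_moves_cost_crossing_right_or_away(self, perf, costs, link):
        out = find_cost_crossing(perf, costs, link)
        inp = find_cost_crossing(perf, costs.replace(cxa_setting="inpatient"), link)
        assert out.status == "found"
        assert inp.status == "none_in_domain" or inp.p_star > out.p_star


class TestOneWaySensitivity:
    def test_null_perturbation_has_zero_shift(self, perf, costs, link):
        table = one_way_sensitivity(
            perf, costs, link,
            [SensitivityScenario("null", "costs.f_cmr", "relative_scale", 1.0)],
        )
        assert table.loc[0, "status"] == "found"
        assert table.loc[0, "shift_percentage_points"] == pytest.approx(0.0, abs=1e-6)

    def test_doubling_fn_complication_rate_shifts_left(self, perf, costs, link):
        table = one_way_sensitivity(
            perf, costs, link,
            [SensitivityScenario("r_f x2", "perf.r_f", "relative_scale", 2.0)],
        )
        assert table.loc[0, "shift_percentage_points"] < 0

    def test_inpatient_swap_shifts_right(self, perf, costs, link):
        table = one_way_sensitivity(
            perf, costs, link,
            [SensitivityScenario("inpatient", perturbation="swap_setting", setting="inpatient")],
        )
        assert table.loc[0, "shift_percentage_points"] > 0

    def test_lower_cmr_sensitivity_shifts_left(self, perf, costs, link):
        table = one_way_sensitivity(
            perf, costs, link,
            [SensitivityScenario("sn 0.80", "perf.sn_cmr", "absolute_set", 0.80)],
        )
        assert table.loc[0, "shift_percentage_points"] < 0

    def test_swap_to_steeper_link_changes_strategy2_cost_monotonically(self, perf, costs, link):
        # the 0.80-FFR-threshold calibration has more FFR-positives at a given
        # stenosis rate -> weakly larger referral fraction -> weakly higher cost2
        steeper = fit_link(
            [LinkPoint(0.1, 0.3), LinkPoint(0.5, 0.7), LinkPoint(0.8, 0.95)],
            form="linear_clipped", ffr_threshold_label="0.80",
        )
        for p in (0.1, 0.5, 0.9):
            assert strategy2_expected_cost(p, perf, costs, steeper) >= strategy2_expected_cost(
                p, perf, costs, link
            )
        table = one_way_sensitivity(
            perf, costs, link,
            [SensitivityScenario("ffr 0.80", perturbation="swap_link", replacement_link=steeper)],
        )
        assert table.loc[0, "status"] == "found"

    def test_scenario_order_does_not_matter(self, perf, costs, link):
        scenarios = [
            SensitivityScenario("a", "costs.f_cmr", "relative_scale", 1.1),
            SensitivityScenario("b", "perf.r_f", "relative_scale", 2.0),
            SensitivityScenario("c", perturbation="swap_setting"),
        ]
        fwd = one_way_sensitivity(perf, costs, link, scenarios)
        rev = one_way_sensitivity(perf, costs, link, scenarios[::-1])
        fwd_by_label = fwd.set_index("label").sort_index()
        rev_by_label = rev.set_index("label").sort_index()
        assert fwd_by_label.equals(rev_by_label)

    def test_out_of_range_probability_clipped_with_warning(self, perf, costs, link):
        with pytest.warns(UserWarning, match="clipped"):
            table = one_way_sensitivity(
                perf, costs, link,
                [SensitivityScenario("sp x1.5", "perf.sp_cmr", "relative_scale", 1.5)],
            )
        assert table.loc[0, "status"] in ("found", "none_in_domain")

    def test_invalid_scenario_reported_not_fatal(self, perf, costs, link):
        with pytest.warns(UserWarning, match="invalid"):
            table = one_way_sensitivity(
                perf, costs, link,
                [
                    SensitivityScenario("bad", "nowhere.field", "absolute_set", 1.0),
                    SensitivityScenario("good", "costs.f_cmr", "relative_scale", 1.0),
                ],
            )
        assert list(table["status"]) == ["invalid", "found"]


def test_default_grid_endpoints():
    grid = default_grid()
    assert grid[0] == pytest.approx(0.10) and grid[-1] == pytest.approx(1.00)
    assert len(grid) == 91
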