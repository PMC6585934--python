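import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kthresh import (
    DiscountSpec,
    adjust_mortality,
    compare_states,
    project_cohort,
    scenario_delta,
)
from kthresh.lifetable import death_year_distribution

from conftest import brute_force_projection, make_toy_inputs

NO_DISC = DiscountSpec(0.0, 0.0)


class TestAdjustMortality:
    def test_zero_elasticity_unchanged(self):
        assert adjust_mortality(0.02, 1.1, 0.0) == pytest.approx(0.02)

    def test_unit_multiplier_unchanged(self):
        assert adjust_mortality(0.02, 1.0, -0.19) == pytest.approx(0.02)

    def test_derived_value_default_mode(self):
        assert adjust_mortality(0.02, 1.1, -0.19) == pytest.approx(0.0196411, abs=1e-6)

    def test_linear_mode(self):
        expected = 0.02 * (1 + 0.9 * (-0.19) * 0.1)
        assert adjust_mortality(0.02, 1.1, -0.19, mode="linear") == pytest.approx(expected)

    def test_linear_mode_negative_rate_errors(self):
        with pytest.raises(ValueError, match="negative rate"):
            adjust_mortality(0.02, 3.0, -1.0, mode="linear")

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="spend_multiplier"):
            adjust_mortality(0.02, 0.0, -0.1)
        with pytest.raises(ValueError, match="unknown adjustment mode"):
            adjust_mortality(0.02, 1.1, -0.1, mode="bogus")


class TestProjectCohort:
    def test_flat_qol_no_discount_equals_life_expectancy(self):
        inputs = make_toy_inputs(n_ages=5, qol_flat=True)
        proj = project_cohort(inputs, 60, "female", NO_DISC)
        assert proj.qalys == pytest.approx(proj.life_years, abs=1e-12)
        assert proj.life_years == pytest.approx(proj.survival.sum(), abs=1e-12)

    def test_one_cycle_world(self):
        # certain death in year 0: enormous hazard, qol(start, 0) = 0.8
        inputs = make_toy_inputs(n_ages=1, cvd=500.0, other=500.0, qol_flat=True)
        inputs.qol["female"][:] = 0.8
        proj = project_cohort(inputs, 60, "female", NO_DISC)
        assert proj.life_years == pytest.approx(1.0, abs=1e-12)
        assert proj.qalys == pytest.approx(0.8, abs=1e-12)

    def test_three_year_lifespan_cost_geometric_sum(self):
        # zero hazard until closure forces death in year 2 (3 years lived)
        inputs = make_toy_inputs(n_ages=3, cvd=0.0, other=0.0, spending=100.0, unrelated=0.0)
        proj = project_cohort(inputs, 60, "female", DiscountSpec(0.04, 0.0))
        expected = 100.0 * (1 + 1 / 1.04 + 1 / 1.04**2)
        assert proj.cvd_cost == pytest.approx(288.6095, abs=1e-4)
        assert proj.cvd_cost == pytest.approx(expected, rel=1e-12)

    def test_death_probabilities_sum_to_one(self):
        inputs = make_toy_inputs(n_ages=5, cvd=0.02, other=0.07)
        proj = project_cohort(inputs, 60, "female", NO_DISC)
        assert proj.death_prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(proj.survival) <= 1e-15)

    def test_qalys_le_life_years(self):
        inputs = make_toy_inputs(n_ages=4, qol_flat=False)
        proj = project_cohort(inputs, 60, "female", NO_DISC)
        assert proj.qalys <= proj.life_years + 1e-12

    def test_constant_hazard_closed_form(self):
        lam = 0.2
        inputs = make_toy_inputs(n_ages=60, cvd=lam / 2, other=lam / 2)
        proj = project_cohort(inputs, 60, "female", NO_DISC)
        q = 1 - np.exp(-lam)
        # discrete closed form: sum_y (1-q)^y = 1/q (minus truncation at closure)
        assert proj.life_years == pytest.approx(1 / q, rel=1e-4)
        # continuous limit within discretization error
        assert abs(proj.life_years - 1 / lam) < 0.6

    def test_missing_age_errors(self):
        inputs = make_toy_inputs(n_ages=3)
        with pytest.raises(ValueError, match="outside the table range|outside"):
            project_cohort(inputs, 55, "female", NO_DISC)


@pytest.mark.parametrize("qol_flat", [True, False])
@pytest.mark.parametrize(
    "discounts", [NO_DISC, DiscountSpec(0.04, 0.015), DiscountSpec(0.04, 0.0)]
)
def test_projection_matches_enumeration_oracle(qol_flat, discounts):
    inputs = make_toy_inputs(
        n_ages=5, cvd=0.04, other=0.09, spending=123.0, unrelated=41.0,
        terminal_mult=6.0, qol_flat=qol_flat,
    )
    proj = project_cohort(inputs, 60, "female", discounts)
    oracle = brute_force_projection(inputs, "female", 60, discounts)
    assert proj.qalys == pytest.approx(oracle["qalys"], rel=1e-10)
    assert proj.life_years == pytest.approx(oracle["life_years"], rel=1e-10)
    assert proj.cvd_cost == pytest.approx(oracle["cvd_cost"], rel=1e-10)
    assert proj.unrelated_cost == pytest.approx(oracle["unrelated_cost"], rel=1e-10)


class TestScenarioDelta:
    def test_zero_elasticity(self):
        inputs = make_toy_inputs(n_ages=4)
        delta = scenario_delta(inputs, 0.0, 0.10, NO_DISC)
        assert delta.delta_qaly == 0.0
        assert delta.delta_ly == 0.0
        # cost delta equals 10% of baseline discounted CVD spending
        base = project_cohort(inputs, 60, "female", NO_DISC)
        assert delta.delta_cost == pytest.approx(0.10 * base.cvd_cost, rel=1e-10)

    def test_negative_elasticity_gains(self):
        inputs = make_toy_inputs(n_ages=6, cvd=0.06)
        delta = scenario_delta(inputs, -0.5, 0.10, NO_DISC)
        assert delta.delta_qaly > 0
        assert delta.delta_ly > 0

    def test_matches_enumeration_oracle(self):
        inputs = make_toy_inputs(
            n_ages=3, cvd=0.05, other=0.08, spending=200.0, unrelated=30.0,
            terminal_mult=4.0, qol_flat=False,
        )
        disc = DiscountSpec(0.04, 0.015)
        e, s = -0.3, 0.10
        delta = scenario_delta(inputs, e, s, disc)
        base = brute_force_projection(inputs, "female", 60, disc)
        alt_rates = [adjust_mortality(r, 1 + s, e) for r in inputs.cvd_mortality["female"]]
        alt_spend = [v * (1 + s) for v in inputs.cvd_spending["female"]]
        alt = brute_force_projection(
            inputs, "female", 60, disc, cvd_override=alt_rates, spending_override=alt_spend
        )
        assert delta.delta_qaly == pytest.approx(alt["qalys"] - base["qalys"], rel=1e-10)
        assert delta.delta_ly == pytest.approx(
            alt["life_years"] - base["life_years"], rel=1e-10
        )
        expected_cost = (alt["cvd_cost"] + alt["unrelated_cost"]) - (
            base["cvd_cost"] + base["unrelated_cost"]
        )
        assert delta.delta_cost == pytest.approx(expected_cost, rel=1e-10)

    @settings(max_examples=15, deadline=None)
    @given(e=st.floats(-1.5, -0.01))
    def test_monotone_in_elasticity_magnitude(self, e):
        inputs = make_toy_inputs(n_ages=5, cvd=0.05)
        d_small = scenario_delta(inputs, e / 2, 0.10, NO_DISC)
        d_large = scenario_delta(inputs, e, 0.10, NO_DISC)
        assert d_large.delta_qaly > d_small.delta_qaly


class TestCompareStates:
    def test_identical_states_zero(self):
        inputs = make_toy_inputs(n_ages=4)
        delta = compare_states(inputs, inputs, NO_DISC)
        assert delta.delta_cost == 0.0
        assert delta.delta_qaly == 0.0
        assert delta.delta_ly == 0.0

    def test_consistency_with_scenario_delta(self):
        import copy

        inputs = make_toy_inputs(n_ages=4, cvd=0.05)
        e, s = -0.4, 0.10
        alt = copy.deepcopy(inputs)
        alt.cvd_mortality["female"] = adjust_mortality(
            inputs.cvd_mortality["female"], 1 + s, e
        )
        alt.cvd_spending["female"] = inputs.cvd_spending["female"] * (1 + s)
        direct = scenario_delta(inputs, e, s, NO_DISC)
        via_states = compare_states(inputs, alt, NO_DISC)
        assert via_states.delta_cost == pytest.approx(direct.delta_cost, rel=1e-12)
        assert via_states.delta_qaly == pytest.approx(direct.delta_qaly, rel=1e-12)

    def test_two_age_example_vs_oracle(self):
        import copy

        disc = DiscountSpec(0.03, 0.01)
        base = make_toy_inputs(n_ages=2, cvd=0.10, other=0.05, spending=80.0, unrelated=20.0)
        alt = copy.deepcopy(base)
        alt.cvd_mortality["female"] = np.array([0.05, 0.04])
        alt.cvd_spending["female"] = np.array([120.0, 130.0])
        delta = compare_states(base, alt, disc)
        ob = brute_force_projection(base, "female", 60, disc)
        oa = brute_force_projection(
            alt, "female", 60, disc,
            cvd_override=alt.cvd_mortality["female"],
            spending_override=alt.cvd_spending["female"],
        )
        assert delta.delta_qaly == pytest.approx(oa["qalys"] - ob["qalys"], rel=1e-10)

    def test_grid_mismatch_errors(self):
        a = make_toy_inputs(n_ages=3)
        b = make_toy_inputs(n_ages=4)
        with pytest.raises(ValueError, match="different age/gender grids"):
            compare_states(a, b, NO_DISC)


def test_death_year_distribution_batched_matches_single():
    rng = np.random.default_rng(0)
    cvd = rng.uniform(0.01, 0.1, size=(4, 6))
    oth = rng.uniform(0.01, 0.1, size=6)
    s_b, q_b, p_b = death_year_distribution(cvd, np.broadcast_to(oth, cvd.shape))
    for k in range(4):
        s, q, p = death_year_distribution(cvd[k], oth)
        np.testing.assert_allclose(p_b[k], p, atol=1e-15)
        np.testing.assert_allclose(s_b[k], s, atol=1e-15)
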