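import math

import numpy as np
import pytest

from smacea import (
    HealthState,
    LifeTable,
    accumulate_outcomes,
    discount_factor,
    dosing_costs,
    run_cohort,
    run_strategy,
    transition_matrix,
)
from smacea.config import (
    CostSet,
    DiscountSpec,
    ModelSpec,
    StrategySpec,
    TransitionSpec,
    UtilitySet,
)
from smacea.markov import ModelError, solve_milestone_prob

NS, SIT, WALK, PAV, DEAD = HealthState


def toy_spec(ns_death=0.0, ns_pav=0.0, pav_death=0.0, utility=1.0,
             state_cost=0.0, rate=0.05, horizon=10.0, lifetable_q=0.0):
    """Minimal immortal-or-simple spec for closed-form checks."""
    tr = TransitionSpec(ns_to_death=ns_death, ns_to_pav=ns_pav,
                        pav_to_death=pav_death,
                        weibull_lambda=1e-12, weibull_p=1.0,
                        weibull_form="rate_years")
    return ModelSpec(
        horizon_years=horizon, start_age_years=0.0,
        discount=DiscountSpec(annual_rate_costs=rate,
                              annual_rate_effects=rate),
        costs=CostSet(state_costs={s: state_cost for s in HealthState
                                   if s != DEAD},
                      acquisition_cost={}, admin_items={}),
        utilities=UtilitySet(utilities={s: utility for s in HealthState
                                        if s != DEAD}),
        transitions={"SOC": tr},
        strategies=[StrategySpec(name="SOC")],
        lifetable=LifeTable(ages=[0.0], annual_qx=[lifetable_q]),
    )


class TestTransitionMatrix:
    def test_soc_not_sitting_row_from_published_inputs(self, base_spec):
        M = transition_matrix(base_spec, base_spec.strategy("SOC"), 1)
        row = M[NS]
        assert row[DEAD] == pytest.approx(0.0532)
        assert row[PAV] == pytest.approx(0.0625)
        assert row[NS] == pytest.approx(1 - 0.0532 - 0.0625)
        assert row[SIT] == row[WALK] == 0.0

    def test_dead_row_is_absorbing(self, base_spec):
        for cycle in (0, 100, 1199):
            M = transition_matrix(base_spec, base_spec.strategy("AVXS-101"),
                                  cycle)
            assert list(M[DEAD]) == [0, 0, 0, 0, 1]

    @pytest.mark.parametrize("strategy", ["SOC", "nusinersen", "AVXS-101"])
    @pytest.mark.parametrize("cycle", [0, 1, 12, 24, 600])
    def test_rows_are_stochastic(self, base_spec, strategy, cycle):
        M = transition_matrix(base_spec, base_spec.strategy(strategy), cycle)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0)

    def test_forbidden_transitions_are_zero(self, base_spec):
        M = transition_matrix(base_spec, base_spec.strategy("AVXS-101"), 5)
        assert M[SIT, NS] == M[SIT, WALK] == M[SIT, PAV] == 0
        assert M[WALK, NS] == M[WALK, SIT] == M[WALK, PAV] == 0
        assert M[PAV, NS] == M[PAV, SIT] == M[PAV, WALK] == 0

    def test_avxs_protected_window_has_no_death_or_pav(self, base_spec):
        M = transition_matrix(base_spec, base_spec.strategy("AVXS-101"), 10)
        assert M[NS, DEAD] == 0.0
        assert M[NS, PAV] == 0.0
        M_post = transition_matrix(base_spec, base_spec.strategy("AVXS-101"),
                                   24)
        assert M_post[NS, DEAD] == pytest.approx(0.0184)
        assert M_post[NS, PAV] == pytest.approx(0.0355)

    def test_cycle_outside_horizon_rejected(self, base_spec):
        with pytest.raises(ModelError):
            transition_matrix(base_spec, base_spec.strategy("SOC"), 1200)


class TestMilestoneSolver:
    def test_no_competing_exit_closed_form(self):
        q = solve_milestone_prob(11 / 12, 24, 0.0)
        assert q == pytest.approx(1 - (1 / 12) ** (1 / 24), rel=1e-10)

    def test_cumulative_inflow_matches_target(self):
        target, window, competing = 0.08, 13, 0.0539
        q = solve_milestone_prob(target, window, competing)
        occ, moved = 1.0, 0.0
        for _ in range(window):
            moved += q * occ
            occ *= 1 - competing - q
        assert moved == pytest.approx(target, abs=1e-12)

    def test_unreachable_fraction_raises(self):
        with pytest.raises(ModelError):
            solve_milestone_prob(0.999, 2, 0.5)


class TestRunCohort:
    def test_first_cycle_equals_matrix_row(self, base_spec):
        trace = run_cohort(base_spec, base_spec.strategy("SOC"))
        M = transition_matrix(base_spec, base_spec.strategy("SOC"), 0)
        assert np.allclose(trace.occupancy[1], M[NS])

    def test_zero_mortality_keeps_everyone_alive(self):
        spec = toy_spec()
        trace = run_cohort(spec, spec.strategy("SOC"))
        assert np.all(trace.occupancy[:, DEAD] == 0.0)

    def test_long_run_absorption_to_death(self, base_spec):
        trace = run_cohort(base_spec, base_spec.strategy("SOC"))
        assert trace.occupancy[-1, DEAD] > 0.999

    @pytest.mark.parametrize("strategy", ["SOC", "nusinersen", "AVXS-101"])
    def test_trace_invariants(self, base_spec, strategy):
        """Rows sum to one within 1e-12 and death is monotone."""
        trace = run_cohort(base_spec, base_spec.strategy(strategy))
        assert trace.n_cycles == 1200
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(trace.occupancy[:, DEAD]) >= -1e-15)
        assert np.all((trace.occupancy >= -1e-15) &
                      (trace.occupancy <= 1 + 1e-12))
        trace.validate()

    def test_avxs_milestone_proportions_reached(self, base_spec):
        trace = run_cohort(base_spec, base_spec.strategy("AVXS-101"))
        occ24 = trace.occupancy[24]
        # milestone states carry their own (tiny) mortality inside the window
        assert occ24[SIT] == pytest.approx(9 / 12, abs=2e-3)
        assert occ24[WALK] == pytest.approx(2 / 12, abs=2e-3)
        assert occ24[DEAD] == pytest.approx(0.0, abs=2e-3)
        assert occ24[PAV] == 0.0


class TestDiscounting:
    @pytest.mark.parametrize("rate,t,expected", [
        (0.05, 1.0, 1 / 1.05),
        (0.0, 37.0, 1.0),
        (0.05, 20.0, 1.05 ** -20),
    ])
    def test_annual_compound_factor(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, rel=1e-12)


class TestAccumulation:
    def test_immortal_cohort_zero_discount_analytic_qalys(self):
        u, T = 0.7, 25.0
        spec = toy_spec(utility=u, rate=0.0, horizon=T)
        out = run_strategy(spec, "SOC")
        assert out.qalys == pytest.approx(u * T, rel=1e-12)
        assert out.life_years == pytest.approx(T, rel=1e-12)

    def test_zero_utility_gives_zero_qalys(self, base_spec):
        import copy

        spec = copy.deepcopy(base_spec)
        for s in HealthState:
            spec.utilities.utilities[s] = 0.0
        out = run_strategy(spec, "SOC")
        assert out.qalys == 0.0

    def test_discounting_reduces_outcomes(self):
        spec0 = toy_spec(utility=0.8, state_cost=100.0, rate=0.0)
        spec5 = toy_spec(utility=0.8, state_cost=100.0, rate=0.05)
        o0 = run_strategy(spec0, "SOC")
        o5 = run_strategy(spec5, "SOC")
        assert o5.qalys < o0.qalys
        assert o5.cost < o0.cost

    def test_soc_base_case_reproduces_published_totals(self, base_result):
        """SOC discounted totals close to the published cohort results."""
        o = base_result.outcomes["SOC"]
        assert o.cost == pytest.approx(923335, rel=0.05)
        assert o.qalys == pytest.approx(0.301, rel=0.05)

    def test_discretisation_stability(self):
        """Halving the cycle length with rescaled probabilities moves
        discounted outcomes by well under 1%."""
        from smacea.survival import rescale_probability

        spec1 = toy_spec(ns_death=0.02, ns_pav=0.03, pav_death=0.01,
                         utility=0.5, state_cost=1000.0, horizon=30.0)
        spec2 = toy_spec(
            ns_death=rescale_probability(0.02, 1.0, 0.5),
            ns_pav=rescale_probability(0.03, 1.0, 0.5),
            pav_death=rescale_probability(0.01, 1.0, 0.5),
            utility=0.5, state_cost=500.0, horizon=30.0)
        spec2.discount.cycle_length_months = 0.5
        o1 = run_strategy(spec1, "SOC")
        o2 = run_strategy(spec2, "SOC")
        assert o2.qalys == pytest.approx(o1.qalys, rel=0.01)
        assert o2.cost == pytest.approx(o1.cost, rel=0.01)


class TestDosingCosts:
    def test_one_off_therapy_charges_full_undiscounted_dose(self, base_spec):
        out = run_strategy(base_spec, "AVXS-101")
        assert out.drug_cost == pytest.approx(3054458.98, abs=1e-6)

    def test_soc_has_no_drug_cost(self, base_spec):
        assert run_strategy(base_spec, "SOC").drug_cost == 0.0

    def test_single_dose_discounted_and_survival_weighted(self):
        """Dose of 100 at 1 year with 50% alive and 5%/yr discounting."""
        spec = toy_spec(rate=0.05, horizon=5.0)
        spec.costs.acquisition_cost["SOC"] = 100.0
        strat = StrategySpec(name="SOC", loading_doses_months=(12.0,))
        trace = run_cohort(spec, strat)
        trace.occupancy[12] = [0.5, 0, 0, 0, 0.5]
        got = dosing_costs(trace, strat, spec)
        assert got == pytest.approx(100 * 0.5 / 1.05, rel=1e-12)

    def test_dose_beyond_horizon_ignored_with_warning(self):
        spec = toy_spec(horizon=1.0)
        spec.costs.acquisition_cost["SOC"] = 100.0
        strat = StrategySpec(name="SOC", loading_doses_months=(24.0,))
        trace = run_cohort(spec, strat)
        with pytest.warns(UserWarning):
            assert dosing_costs(trace, strat, spec) == 0.0

    def test_nusinersen_doses_not_charged_in_pav(self, base_spec):
        assert PAV not in base_spec.strategy("nusinersen").dosed_states
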