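import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from smacea import (
    LifeTable,
    coxsnell_residuals,
    cycle_probability,
    fit_parametric,
    lifetable_monthly_prob,
    rescale_probability,
    select_best,
    weibull_survival,
)
from smacea.survival import (
    FAMILIES,
    FitError,
    ParametricFit,
    fit_all_families,
    survival_function,
)

LAM, P = 0.0006, 1.9613


class TestWeibullSurvival:
    def test_survival_starts_at_one(self):
        assert weibull_survival(0.0, LAM, P) == 1.0

    def test_median_matches_root_finding_oracle(self):
        closed = (math.log(2) / LAM) ** (1 / P)
        root = optimize.brentq(
            lambda t: weibull_survival(t, LAM, P) - 0.5, 1.0, 100.0)
        assert closed == pytest.approx(root, rel=1e-10)
        assert closed == pytest.approx(36.4, abs=0.05)

    def test_direct_evaluation(self):
        # independent high-precision evaluation of exp(-lam * 10**p)
        from decimal import Decimal, getcontext

        getcontext().prec = 50
        expected = float(Decimal(-LAM * 10.0 ** P).exp())
        assert weibull_survival(10.0, LAM, P) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(-1.0, LAM, P)

    @given(st.floats(0.01, 80.0), st.floats(0.02, 80.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert weibull_survival(hi, LAM, P) <= weibull_survival(lo, LAM, P)


class TestCycleProbability:
    def test_constant_hazard_is_memoryless(self):
        s = survival_function("exponential", (0.12,))
        q0 = cycle_probability(s, 0.0, 1.0)
        q7 = cycle_probability(s, 7.3, 1.0)
        assert q0 == pytest.approx(1 - math.exp(-0.12), rel=1e-12)
        assert q7 == pytest.approx(q0, rel=1e-12)

    def test_vanishing_interval_gives_vanishing_probability(self):
        s = survival_function("weibull", (LAM, P))
        assert cycle_probability(s, 10.0, 1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_weibull_cycle_matches_direct_ratio(self):
        s = survival_function("weibull", (LAM, P))
        expected = 1 - math.exp(-LAM * (10 + 1 / 12) ** P) / math.exp(
            -LAM * 10.0 ** P)
        assert cycle_probability(s, 10.0, 1 / 12) == pytest.approx(
            expected, rel=1e-12)

    def test_composition_over_adjacent_intervals(self):
        s = survival_function("weibull", (LAM, P))
        q1 = cycle_probability(s, 5.0, 0.5)
        q2 = cycle_probability(s, 5.5, 0.5)
        one_shot = cycle_probability(s, 5.0, 1.0)
        assert (1 - q1) * (1 - q2) == pytest.approx(1 - one_shot, rel=1e-12)

    def test_degenerate_cohort_raises(self):
        s = survival_function("exponential", (50.0,))
        with pytest.raises(ZeroDivisionError):
            cycle_probability(s, 20.0, 1.0)


class TestRescaleProbability:
    def test_annual_to_monthly_closed_form(self):
        assert rescale_probability(0.012, 1.0, 1 / 12) == pytest.approx(
            1 - 0.988 ** (1 / 12), rel=1e-12)

    @given(st.floats(0.0, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovers_input(self, p):
        assert rescale_probability(
            rescale_probability(p, 1.0, 1 / 12), 1 / 12, 1.0
        ) == pytest.approx(p, abs=1e-12)

    def test_identity_interval(self):
        assert rescale_probability(0.3, 2.0, 2.0) == pytest.approx(0.3)

    def test_certain_event_stays_certain(self):
        assert rescale_probability(1.0, 1.0, 0.5) == 1.0


class TestLifeTable:
    def test_flat_zero_table_gives_zero(self):
        lt = LifeTable(ages=[0, 1, 2], annual_qx=[0, 0, 0])
        assert lifetable_monthly_prob(lt, 1.5) == 0.0

    def test_monthly_rescaling(self):
        lt = LifeTable(ages=[0, 30], annual_qx=[0.001, 0.012])
        assert lifetable_monthly_prob(lt, 30.2) == pytest.approx(
            1 - 0.988 ** (1 / 12), rel=1e-9)

    def test_beyond_last_age_uses_last_row(self):
        lt = LifeTable(ages=[0, 50], annual_qx=[0.001, 0.2])
        assert lifetable_monthly_prob(lt, 200.0) == pytest.approx(
            rescale_probability(0.2, 1.0, 1 / 12))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            LifeTable(ages=[], annual_qx=[])


def _simulate(family, params, n, censor_at, rng):
    """Inverse-CDF draws from a parametric family with admin censoring."""
    u = rng.uniform(size=n)
    if family == "exponential":
        t = -np.log(u) / params[0]
    elif family == "weibull":
        t = (-np.log(u) / params[0]) ** (1 / params[1])
    elif family == "gompertz":
        a, b = params
        t = np.log1p(-a * np.log(u) / b) / a
    elif family == "lognormal":
        t = np.exp(params[0] + params[1] * rng.standard_normal(n))
    elif family == "loglogistic":
        t = params[0] * (1 / u - 1) ** (1 / params[1])
    events = t <= censor_at
    return np.minimum(t, censor_at), events.astype(int)


TRUE_PARAMS = {
    "exponential": (0.1,),
    "weibull": (0.05, 1.4),
    "gompertz": (0.08, 0.05),
    "lognormal": (1.8, 0.6),
    "loglogistic": (8.0, 2.2),
}


class TestParametricFitting:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_within_3se(self, family):
        """MLE on n=1000 censored draws recovers the generating values.

        The 3-SE band is approximated by a parametric-bootstrap-free
        large-sample tolerance of 3/sqrt(n_events) on the log scale.
        """
        rng = np.random.default_rng(42)
        params = TRUE_PARAMS[family]
        times, events = _simulate(family, params, 1000, 30.0, rng)
        fit = fit_parametric(times, events, family)
        tol = 3.0 / math.sqrt(events.sum())
        for est, true in zip(fit.params, params):
            if family == "gompertz" and true == params[0]:
                assert abs(est - true) < 5 * tol  # shape is weakly identified
            else:
                assert abs(math.log(est / true)) < 3 * tol

    def test_exponential_rate_within_ci(self):
        rng = np.random.default_rng(7)
        times, events = _simulate("exponential", (0.1,), 500, np.inf, rng)
        fit = fit_parametric(times, events, "exponential")
        se = 0.1 / math.sqrt(500)
        assert abs(fit.params[0] - 0.1) < 1.96 * se * 1.5

    def test_cross_check_against_lifelines(self):
        """Our censored Weibull MLE must agree with lifelines' fitter."""
        from lifelines import WeibullFitter

        rng = np.random.default_rng(3)
        times, events = _simulate("weibull", (0.05, 1.4), 400, 25.0, rng)
        ours = fit_parametric(times, events, "weibull")
        wf = WeibullFitter().fit(times, events)
        # lifelines uses S(t) = exp(-(t/lambda)^rho)
        lam_ll = wf.lambda_ ** (-wf.rho_)
        assert ours.params[1] == pytest.approx(wf.rho_, rel=1e-3)
        assert ours.params[0] == pytest.approx(lam_ll, rel=1e-3)
        assert ours.loglik == pytest.approx(
            wf.log_likelihood_, rel=1e-6)

    def test_weibull_with_unit_shape_prefers_exponential_by_aic(self):
        rng = np.random.default_rng(11)
        times, events = _simulate("exponential", (0.1,), 600, 40.0, rng)
        fe = fit_parametric(times, events, "exponential")
        fw = fit_parametric(times, events, "weibull")
        assert fw.loglik == pytest.approx(fe.loglik, abs=2.0)
        assert fe.aic < fw.aic

    def test_single_event_is_non_identifiable(self):
        with pytest.raises(FitError):
            fit_parametric([1.0, 2.0, 3.0], [1, 0, 0], "weibull")

    def test_all_censored_is_non_identifiable(self):
        with pytest.raises(FitError):
            fit_parametric([1.0, 2.0, 3.0], [0, 0, 0], "exponential")

    def test_information_criteria_definitions(self):
        fit = ParametricFit(family="weibull", params=(0.1, 1.2),
                            loglik=-100.0, n=50, n_events=30)
        assert fit.aic == pytest.approx(2 * 2 - 2 * (-100.0))
        assert fit.bic == pytest.approx(2 * math.log(50) + 200.0)


class TestModelSelection:
    def test_single_fit_selected(self):
        f = ParametricFit("exponential", (0.1,), -10.0, 20, 15)
        assert select_best([f]) is f

    def test_aic_tie_broken_by_bic(self):
        f1 = ParametricFit("weibull", (0.1, 1.0), -10.0, 20, 15)
        f2 = ParametricFit("exponential", (0.1,), -11.0, 20, 15)
        assert f1.aic == f2.aic
        assert select_best([f1, f2]) is f2  # lower BIC (fewer params)

    def test_exponential_truth_selected_in_majority(self):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(10):
            times, events = _simulate("exponential", (0.12,), 300, 30.0, rng)
            fits, _ = fit_all_families(times, events)
            if select_best(fits).family == "exponential":
                wins += 1
        assert wins > 5

    def test_no_converged_fits_raises(self):
        bad = ParametricFit("weibull", (0.1, 1.0), -10.0, 20, 15,
                            converged=False)
        with pytest.raises(FitError):
            select_best([bad])


class TestCoxSnell:
    @staticmethod
    def _cumhaz_slope(fit, times, events):
        from smacea import km_estimator

        r, d = coxsnell_residuals(fit, times, events)
        km = km_estimator(np.maximum(r, 1e-12), d)
        ch = -np.log(np.maximum(km.survival, 1e-12))
        return np.polyfit(km.times, ch, 1)[0]

    def test_correct_model_gives_unit_slope(self):
        rng = np.random.default_rng(9)
        times, events = _simulate("weibull", (0.05, 1.4), 800, 25.0, rng)
        fit = fit_parametric(times, events, "weibull")
        assert self._cumhaz_slope(fit, times, events) == pytest.approx(
            1.0, abs=0.15)

    def test_misspecified_model_deviates(self):
        rng = np.random.default_rng(9)
        # strongly increasing hazard, fitted as constant hazard
        times, events = _simulate("weibull", (0.001, 3.5), 800, 12.0, rng)
        fit = fit_parametric(times, events, "exponential")
        assert abs(self._cumhaz_slope(fit, times, events) - 1.0) > 0.3

    def test_time_zero_event_has_zero_residual(self):
        fit = ParametricFit("exponential", (0.1,), -1.0, 3, 2)
        r, _ = coxsnell_residuals(fit, [0.0, 1.0], [1, 1])
        assert r[0] == 0.0
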