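"""Censored exponential fits, rate regressions, and binding isotherms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spireformin import (
    EndState,
    branch_model_uncapping,
    fit_binding_isotherm,
    fit_displacing_rate,
    fit_exponential_rate,
    fit_second_order_rate,
    invert_kobs_capping_of_BF,
    kobs_capping_of_BF,
)
from spireformin.model import RateConstants
from spireformin.synth import ExperimentDesign, generate_switch_experiment


class TestExponentialRate:
    def test_mle_closed_form(self):
        fit = fit_exponential_rate([10.0, 10.0, 10.0])
        assert fit.estimate == pytest.approx(0.1, rel=1e-12)

    def test_single_event(self):
        fit = fit_exponential_rate([100.0])
        assert fit.estimate == pytest.approx(0.01)
        assert fit.ci[1] / fit.ci[0] > 10  # wide CI from one event

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            fit_exponential_rate([300.0, 300.0], censored=[True, True])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.1, 500.0), min_size=2, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_mle_equals_count_over_total_time(self, times, seed):
        rng = np.random.default_rng(seed)
        cens = rng.random(len(times)) < 0.3
        if cens.all():
            cens[0] = False
        fit = fit_exponential_rate(times, cens)
        assert fit.estimate == pytest.approx((~cens).sum() / np.sum(times), rel=1e-12)

    def test_censored_recovery(self):
        """500 dwells at 0.0101 /s censored at 300 s: within 10%, CI covers."""
        rng = np.random.default_rng(2026)
        t = rng.exponential(1 / 0.0101, 500)
        cens = t > 300
        t = np.minimum(t, 300.0)
        fit = fit_exponential_rate(t, cens)
        assert 0.03 < cens.mean() < 0.15
        assert fit.estimate == pytest.approx(0.0101, rel=0.10)
        assert fit.ci[0] <= 0.0101 <= fit.ci[1]

    def test_least_squares_mode_agrees(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(100.0, 400)
        mle = fit_exponential_rate(t)
        ls = fit_exponential_rate(t, method="ls")
        assert ls.method == "least-squares"
        assert ls.estimate == pytest.approx(mle.estimate, rel=0.1)


class TestSecondOrderRate:
    def test_exact_line(self):
        c = np.array([2.5, 5, 10, 20]) * 1e-3
        fit = fit_second_order_rate(c, 2.7 * c)
        assert fit.estimate == pytest.approx(2.7, rel=1e-12)

    def test_single_point_through_origin(self):
        fit = fit_second_order_rate([0.01], [0.027])
        assert fit.estimate == pytest.approx(2.7)

    def test_rank_deficiency_with_intercept(self):
        with pytest.raises(ValueError, match="rank deficient"):
            fit_second_order_rate([0.01, 0.01], [0.02, 0.03], through_origin=False)

    def test_intercept_mode_reports_intercept(self):
        c = np.array([1, 2, 3, 4.0])
        fit = fit_second_order_rate(c, 2.0 * c + 0.5, through_origin=False)
        assert fit.estimate == pytest.approx(2.0)
        assert fit.extra["intercept"] == pytest.approx(0.5)


class TestCompositeCappingRate:
    def test_printed_formula_value(self, rc):
        k_app = 0.396 * 0.04
        assert kobs_capping_of_BF(k_app, 0.04, rc) == pytest.approx(0.0185, abs=2e-4)

    def test_limits(self, rc):
        fast_off = RateConstants(k_off_F=1e-12)
        assert kobs_capping_of_BF(0.01, 0.04, fast_off) == pytest.approx(0.01, rel=1e-6)
        high_s = kobs_capping_of_BF(0.01, 1e6, rc)
        assert high_s == pytest.approx(0.01 + rc.k_off_F, rel=1e-6)

    def test_zero_denominator_rejected(self):
        rc0 = RateConstants(k_off_F=0.0)
        with pytest.raises(ValueError):
            kobs_capping_of_BF(0.01, 0.0, rc0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.floats(1e-5, 1.0), st.floats(1e-4, 1.0))
    def test_inverse_composes_to_identity(self, k_app, s):
        rc = RateConstants()
        kobs = kobs_capping_of_BF(k_app, s, rc)
        assert invert_kobs_capping_of_BF(kobs, s, rc) == pytest.approx(k_app, abs=1e-10)


class TestBranchModel:
    def test_printed_fractions(self, rc):
        total, f_b, f_bf = branch_model_uncapping(rc, 0.01)
        assert total == pytest.approx(0.0130, abs=1e-4)
        assert f_bf == pytest.approx(0.223, abs=0.002)
        total, _, f_bf = branch_model_uncapping(rc, 0.02)
        assert f_bf == pytest.approx(0.365, abs=0.002)

    def test_zero_formin(self, rc):
        _, f_b, f_bf = branch_model_uncapping(rc, 0.0)
        assert (f_b, f_bf) == (1.0, 0.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(0, 10.0))
    def test_fractions_sum_to_one(self, f):
        _, f_b, f_bf = branch_model_uncapping(RateConstants(), f)
        assert f_b + f_bf == pytest.approx(1.0, abs=1e-12)


class TestDisplacingRate:
    def test_formin_on_spire_capped_recovery(self, rc):
        des = ExperimentDesign("switch", (0.010, 0.020), 150, 900.0, seed=5)
        events = generate_switch_experiment(des, rc, EndState.SPIRE_CAPPED)
        fit = fit_displacing_rate(events, "F_on_BS", rc)
        assert fit.estimate == pytest.approx(rc.k_on_F_displacing, rel=0.15)

    def test_spire_on_formin_bound_recovery(self, rc):
        des = ExperimentDesign("switch", (0.020, 0.040), 150, 900.0, seed=6)
        events = generate_switch_experiment(des, rc, EndState.FORMIN_BOUND)
        fit = fit_displacing_rate(events, "S_on_BF", rc)
        assert fit.estimate == pytest.approx(rc.k_on_S_displacing, rel=0.15)

    def test_null_displacement_ci_covers_zero(self, rc):
        rc0 = RateConstants(k_on_F_displacing=0.0)
        des = ExperimentDesign("switch", (0.020,), 150, 900.0, seed=7)
        events = generate_switch_experiment(des, rc0, EndState.SPIRE_CAPPED)
        fit = fit_displacing_rate(events, "F_on_BS", rc0)
        assert fit.estimate == 0.0
        assert fit.ci[0] <= 0.0 <= fit.ci[1]

    def test_wrong_initial_state_rejected(self, rc):
        events = pd.DataFrame({"filament_id": [0], "initial_state": ["FREE"],
                               "destination": ["SPIRE_CAPPED"],
                               "waiting_time_s": [10.0], "censored": [False],
                               "spire_uM": [0.02]})
        with pytest.raises(ValueError):
            fit_displacing_rate(events, "S_on_BF", rc)


class TestBindingIsotherm:
    def test_noiseless_exact_recovery(self):
        c = np.array([0.5, 1, 2, 4, 8, 16, 32, 100.0])
        rates = 1.0 - 0.5 * c / (c + 6.0)
        fit = fit_binding_isotherm(c, rates)
        assert fit.estimate == pytest.approx(6.0, rel=1e-5)
        assert fit.extra["plateau"] == pytest.approx(0.5, abs=1e-5)

    def test_midpoint_at_kd(self):
        c = np.array([0.5, 1, 2, 4, 6, 8, 16, 32, 100.0])
        rates = 1.0 - 0.6 * c / (c + 6.0)
        fit = fit_binding_isotherm(c, rates)
        top, plateau = 1.0, fit.extra["plateau"]
        midpoint = top - 0.6 * 0.5
        idx = np.where(c == 6.0)[0][0]
        assert rates[idx] == pytest.approx(midpoint)

    def test_noisy_recovery_with_many_replicates(self):
        """8 concentrations x 100 replicates, 5% multiplicative noise."""
        rng = np.random.default_rng(11)
        grid = np.array([0.5, 1, 2, 4, 8, 16, 32, 100.0])
        c = np.repeat(grid, 100)
        sigma = np.sqrt(np.log1p(0.05**2))
        noise = rng.lognormal(-sigma**2 / 2, sigma, len(c))
        rates = (1.0 - 0.5 * c / (c + 6.0)) * noise
        fit = fit_binding_isotherm(c, rates)
        assert fit.estimate == pytest.approx(6.0, rel=0.25)
        assert fit.ci[0] <= 6.0 <= fit.ci[1]

    def test_quadratic_tight_reduces_to_hyperbolic_at_low_ends(self):
        c = np.array([0.5, 1, 2, 4, 8, 16, 32, 100.0])
        rates = 1.0 - 0.8 * c / (c + 6.0)
        fit = fit_binding_isotherm(c, rates, model="quadratic_tight", ends_nM=1e-4)
        assert fit.estimate == pytest.approx(6.0, rel=1e-3)

    def test_needs_three_concentrations(self):
        with pytest.raises(ValueError):
            fit_binding_isotherm([1.0, 2.0], [0.9, 0.8])
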