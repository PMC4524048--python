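"""Survival curves: closed forms, fitting, selection, PH transforms."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pscea import (
    FitResult,
    FittingError,
    HazardRatioChain,
    IpdSimSpec,
    ParametricSurvival,
    apply_hazard_ratio,
    exponential_from_landmark,
    fit_all_families,
    fit_exponential_endpoint,
    fit_parametric,
    select_best_fit,
    simulate_ipd,
    survival_at,
)
from pscea.io import IPDTable

GRID = np.linspace(0.0, 200.0, 401)


def _random_curve(rng):
    family = rng.choice(["exponential", "weibull", "gompertz", "loglogistic"])
    if family == "exponential":
        return ParametricSurvival.exponential(rng.uniform(0.02, 0.3))
    if family == "weibull":
        return ParametricSurvival.weibull(rng.uniform(0.5, 3.0), rng.uniform(3, 40))
    if family == "gompertz":
        return ParametricSurvival.gompertz(rng.uniform(0.005, 0.2), rng.uniform(0.005, 0.1))
    return ParametricSurvival.loglogistic(rng.uniform(0.8, 3.0), rng.uniform(3, 40))


# ---------------------------------------------------------------------------
# survival_at / closed forms
# ---------------------------------------------------------------------------


class TestSurvivalForms:
    def test_starts_at_one_for_every_family(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert _random_curve(rng).sf(0.0) == pytest.approx(1.0)

    def test_weibull_shape_one_is_exponential(self):
        weib = ParametricSurvival.weibull(1.0, 10.0)
        expo = ParametricSurvival.exponential(0.1)
        assert weib.sf(10.0) == pytest.approx(math.exp(-1.0), abs=1e-12)
        assert np.allclose(weib.sf(GRID), expo.sf(GRID), atol=1e-12)

    def test_weibull_median_closed_form_matches_root_finding(self):
        curve = ParametricSurvival.weibull(2.0, 12.0)
        expected = 12.0 * math.log(2.0) ** 0.5  # ~9.99 months
        assert curve.median() == pytest.approx(expected, abs=1e-9)
        # independent numeric oracle: bisect S(t) = 0.5
        from scipy.optimize import brentq

        root = brentq(lambda t: curve.sf(t) - 0.5, 1e-9, 100.0)
        assert curve.median() == pytest.approx(root, abs=1e-7)

    @pytest.mark.parametrize("family,params", [
        ("exponential", (0.08,)),
        ("weibull", (1.4, 12.0)),
        ("gompertz", (0.05, 0.01)),
        ("loglogistic", (1.8, 9.0)),
    ])
    def test_median_closed_forms_agree_with_sf(self, family, params):
        curve = ParametricSurvival(family, params)
        assert curve.sf(curve.median()) == pytest.approx(0.5, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            survival_at(ParametricSurvival.exponential(0.1), -1.0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ParametricSurvival.gompertz(-0.1, 0.05)  # cure-fraction shape
        with pytest.raises(ValueError, match="positive"):
            ParametricSurvival.exponential(0.0)

    @given(st.sampled_from(["exponential", "weibull", "gompertz", "loglogistic"]),
           st.integers(min_value=0, max_value=10_000))
    def test_monotone_and_bounded_on_dense_grid(self, family, seed):
        curve = None
        rng = np.random.default_rng(seed)
        while curve is None or curve.family != family:
            curve = _random_curve(rng)
        s = curve.sf(GRID)
        assert np.all((0.0 <= s) & (s <= 1.0))
        assert np.all(np.diff(s) <= 1e-12)


# ---------------------------------------------------------------------------
# proportional hazards
# ---------------------------------------------------------------------------


class TestHazardRatios:
    def test_unit_chain_is_identity(self):
        base = ParametricSurvival.weibull(1.3, 10.0)
        out = apply_hazard_ratio(base, HazardRatioChain.single(1.0))
        assert np.allclose(out.sf(GRID), base.sf(GRID))

    def test_exponential_hr_two_halves_median(self):
        base = ParametricSurvival.exponential(0.05)
        out = apply_hazard_ratio(base, 2.0)
        assert out.family == "exponential"
        assert out.params[0] == pytest.approx(0.1)
        assert out.median() == pytest.approx(base.median() / 2.0, rel=1e-12)

    def test_chain_product_cancels_to_identity(self):
        chain = HazardRatioChain((("up", 1.25), ("down", 0.80)))
        assert chain.combined_hr == pytest.approx(1.0)
        base = ParametricSurvival.loglogistic(1.5, 8.0)
        out = apply_hazard_ratio(base, chain)
        assert np.allclose(out.sf(GRID), base.sf(GRID))

    def test_closed_form_families_match_power_transform(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            base = _random_curve(rng)
            hr = rng.uniform(0.3, 3.0)
            out = apply_hazard_ratio(base, hr)
            assert np.allclose(out.sf(GRID), base.sf(GRID) ** hr, atol=1e-10)
            s = out.sf(GRID)
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            apply_hazard_ratio(ParametricSurvival.exponential(0.1), 0.0)
        with pytest.raises(ValueError, match="> 0"):
            HazardRatioChain((("bad", -1.0),))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFitting:
    def test_exponential_mle_matches_lifelines(self, censored_weibull_ipd):
        from lifelines import ExponentialFitter

        ipd = censored_weibull_ipd
        fit = fit_parametric(ipd, "exponential")
        assert fit.curve.params[0] == pytest.approx(
            ipd.n_events / ipd.time.sum(), rel=1e-12
        )
        oracle = ExponentialFitter().fit(ipd.time, ipd.event)
        assert fit.curve.params[0] == pytest.approx(1.0 / oracle.lambda_, rel=1e-6)
        assert fit.log_likelihood == pytest.approx(oracle.log_likelihood_, rel=1e-6)

    def test_weibull_mle_matches_lifelines(self, censored_weibull_ipd):
        from lifelines import WeibullFitter

        ipd = censored_weibull_ipd
        fit = fit_parametric(ipd, "weibull")
        oracle = WeibullFitter().fit(ipd.time, ipd.event)
        assert fit.curve.param_dict["shape"] == pytest.approx(oracle.rho_, rel=1e-4)
        assert fit.curve.param_dict["scale"] == pytest.approx(oracle.lambda_, rel=1e-4)

    def test_loglogistic_mle_matches_lifelines(self, censored_weibull_ipd):
        from lifelines import LogLogisticFitter

        ipd = censored_weibull_ipd
        fit = fit_parametric(ipd, "loglogistic")
        oracle = LogLogisticFitter().fit(ipd.time, ipd.event)
        assert fit.curve.param_dict["shape"] == pytest.approx(oracle.beta_, rel=1e-4)
        assert fit.curve.param_dict["scale"] == pytest.approx(oracle.alpha_, rel=1e-4)

    def test_weibull_parameter_recovery(self, censored_weibull_ipd):
        fit = fit_parametric(censored_weibull_ipd, "weibull")
        assert fit.curve.param_dict["shape"] == pytest.approx(1.3, abs=0.1)
        assert fit.curve.param_dict["scale"] == pytest.approx(10.0, abs=0.5)

    def test_recovery_bias_shrinks_with_sample_size(self):
        errors = []
        for n in (200, 1000, 5000):
            shape_err = []
            for seed in range(3):
                ipd = simulate_ipd(IpdSimSpec(
                    n=n, family="weibull", params=(1.3, 10.0),
                    random_censor_frac=0.2, seed=1000 + seed))
                fit = fit_parametric(ipd, "weibull")
                shape_err.append(abs(fit.curve.param_dict["shape"] - 1.3))
            errors.append(np.mean(shape_err))
        assert errors[2] < errors[0]

    def test_weibull_nests_exponential(self, censored_weibull_ipd):
        fits = {f.curve.family: f for f in fit_all_families(censored_weibull_ipd)}
        assert fits["weibull"].log_likelihood >= fits["exponential"].log_likelihood
        assert fits["weibull"].aic == pytest.approx(
            2 * 2 - 2 * fits["weibull"].log_likelihood
        )

    def test_weibull_fit_to_exponential_data_has_unit_shape(self):
        ipd = simulate_ipd(IpdSimSpec(
            n=5000, family="exponential", params=(0.1,), seed=11))
        fit = fit_parametric(ipd, "weibull")
        assert fit.curve.param_dict["shape"] == pytest.approx(1.0, abs=0.05)

    def test_all_censored_data_rejected(self):
        ipd = IPDTable(np.linspace(1, 10, 10), np.zeros(10, dtype=int))
        with pytest.raises(FittingError, match="censored"):
            fit_parametric(ipd, "weibull")

    def test_single_event_rejected(self):
        ipd = IPDTable(np.linspace(1, 10, 10),
                       np.array([1] + [0] * 9))
        with pytest.raises(FittingError, match="2 observed events"):
            fit_parametric(ipd, "exponential")

    def test_unknown_family_rejected(self, censored_weibull_ipd):
        with pytest.raises(ValueError, match="unknown family"):
            fit_parametric(censored_weibull_ipd, "lognormal")


class TestSelection:
    @staticmethod
    def _fit(family, params, aic, n_events=80, n_censored=20):
        ll = (2 * len(params) - aic) / 2.0
        return FitResult(ParametricSurvival(family, params), ll, aic,
                         aic + 1.0, n_events, n_censored)

    def test_minimum_aic_wins(self):
        fits = [self._fit("exponential", (0.1,), 102.1),
                self._fit("weibull", (1.2, 10.0), 99.4),
                self._fit("loglogistic", (1.5, 8.0), 105.0)]
        assert select_best_fit(fits).aic == 99.4

    def test_aic_tie_prefers_fewer_parameters(self):
        fits = [self._fit("weibull", (1.2, 10.0), 100.0),
                self._fit("exponential", (0.1,), 100.0)]
        assert select_best_fit(fits).curve.family == "exponential"

    def test_mismatched_datasets_rejected(self):
        fits = [self._fit("exponential", (0.1,), 100.0, n_events=50),
                self._fit("weibull", (1.2, 10.0), 99.0, n_events=80)]
        with pytest.raises(FittingError, match="different datasets"):
            select_best_fit(fits)

    def test_true_family_selected_on_large_samples(self):
        # markedly non-exponential truth: the correct family should win
        # the AIC race on every one of a handful of seeds
        wins = 0
        for seed in range(5):
            ipd = simulate_ipd(IpdSimSpec(
                n=5000, family="weibull", params=(1.8, 10.0),
                random_censor_frac=0.2, seed=500 + seed))
            best = select_best_fit(fit_all_families(ipd))
            wins += best.curve.family == "weibull"
        assert wins >= 5 * 0.95


class TestExponentialEndpoint:
    def test_landmark_rate_closed_form(self):
        curve = exponential_from_landmark(12.0, 0.5)
        assert curve.params[0] == pytest.approx(math.log(2.0) / 12.0)
        assert curve.sf(12.0) == pytest.approx(0.5)

    def test_landmark_inputs_validated(self):
        with pytest.raises(ValueError):
            exponential_from_landmark(0.0, 0.5)
        with pytest.raises(ValueError):
            exponential_from_landmark(12.0, 1.0)

    def test_endpoint_fit_recovers_exponential_truth(self):
        ipd = simulate_ipd(IpdSimSpec(
            n=4000, family="exponential", params=(0.08,),
            admin_cutoff_months=30.0, seed=21))
        fit = fit_exponential_endpoint(ipd, landmark_months=12.0)
        assert fit.curve.params[0] == pytest.approx(0.08, rel=0.1)
        # both exponential modes agree on exponential data
        ml = fit_parametric(ipd, "exponential")
        assert fit.curve.params[0] == pytest.approx(ml.curve.params[0], rel=0.1)
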