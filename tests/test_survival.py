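"""Parametric survival: evaluation, censored MLE, AIC selection, PH effects."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adtcea.survival import (FAMILIES, AllCensoredError, HazardRatio,
                             SurvivalDataset, SurvivalFit, apply_hazard_ratio,
                             fit_all_families, fit_parametric, fit_report,
                             per_cycle_progression_prob,
                             per_cycle_progression_probs, select_best,
                             survival_at)
from adtcea.synthetic import GeneratorSpec, gen_survival


def _fit(family, shape, scale):
    return SurvivalFit(family=family, shape=shape, scale=scale,
                       log_likelihood=0.0, aic=0.0,
                       n_params=1 if family == "exponential" else 2)


class TestSurvivalAt:
    @pytest.mark.parametrize("family,shape,scale,t,expected", [
        ("loglogistic", 1.0, 1.0, 1.0, 0.5),
        ("exponential", None, 0.01, 100.0, math.exp(-1.0)),
        ("weibull", 2.0, 1e-4, 100.0, math.exp(-1.0)),
        ("gompertz", 0.01, 0.001, 0.0, 1.0),
    ])
    def test_closed_forms(self, family, shape, scale, t, expected):
        assert survival_at(_fit(family, shape, scale), t) == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("family,shape,scale", [
        ("exponential", None, 0.01), ("weibull", 1.3, 1e-3),
        ("loglogistic", 1.5, 0.005), ("lognormal", 1.1, 3.5),
        ("gompertz", 1e-3, 0.01),
    ])
    def test_starts_at_one_and_non_increasing(self, family, shape, scale):
        fit = _fit(family, shape, scale)
        grid = np.linspace(0.0, 2000.0, 200)
        s = survival_at(fit, grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((0.0 <= s) & (s <= 1.0))

    def test_negative_shape_gompertz_plateaus(self):
        # A defective Gompertz curve levels off at exp(lambda/gamma) > 0.
        fit = _fit("gompertz", -0.01, 0.001)
        assert survival_at(fit, 1e6) == pytest.approx(
            math.exp(0.001 / -0.01), rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(_fit("exponential", None, 0.01), -1.0)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            survival_at(_fit("weibull", math.nan, 0.01), 1.0)


class TestFitting:
    def test_exponential_mle_matches_events_over_exposure(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(100.0, size=400)
        events = np.ones_like(times)
        data = SurvivalDataset(times, events)
        fit = fit_parametric(data, "exponential")
        closed_form = data.n_events / data.exposure
        assert fit.scale == pytest.approx(closed_form, rel=1e-8)

    def test_exponential_mle_closed_form_under_censoring(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(100.0, size=500)
        events = (rng.random(500) < 0.7).astype(int)
        data = SurvivalDataset(times, events)
        fit = fit_parametric(data, "exponential")
        assert fit.scale == pytest.approx(data.n_events / data.exposure,
                                          rel=1e-8)

    def test_loglogistic_parameter_recovery(self):
        spec = GeneratorSpec(family="loglogistic", shape=1.5, scale=0.005,
                             n=2000, dropout_frac=0.2, seed=7)
        ref, _ = gen_survival(spec)
        fit = fit_parametric(ref, "loglogistic")
        assert fit.shape == pytest.approx(1.5, rel=0.10)
        assert fit.scale == pytest.approx(0.005, rel=0.10)

    def test_loglik_at_mle_beats_generating_parameters(self):
        from adtcea.survival import _log_hazard, _log_survival
        spec = GeneratorSpec(family="loglogistic", shape=1.5, scale=0.005,
                             n=1000, seed=21)
        ref, _ = gen_survival(spec)
        fit = fit_parametric(ref, "loglogistic")
        # censored log-likelihood evaluated at the generating parameters
        ls = _log_survival("loglogistic", ref.times, 1.5, 0.005).sum()
        lh = _log_hazard("loglogistic", ref.times[ref.events == 1],
                         1.5, 0.005).sum()
        assert fit.log_likelihood >= ls + lh - 1e-6

    def test_aic_identity(self):
        spec = GeneratorSpec(n=500, seed=3)
        ref, _ = gen_survival(spec)
        for fam in FAMILIES:
            fit = fit_parametric(ref, fam)
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.log_likelihood, abs=1e-9)

    def test_all_censored_raises(self):
        data = SurvivalDataset([10.0, 20.0], [0, 0])
        with pytest.raises(AllCensoredError):
            fit_parametric(data, "weibull")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SurvivalDataset([1.0, -2.0], [1, 1])
        with pytest.raises(ValueError):
            SurvivalDataset([1.0, 2.0], [1, 2])
        with pytest.raises(ValueError):
            SurvivalDataset([], [])
        with pytest.raises(ValueError):
            fit_parametric(SurvivalDataset([1.0], [1]), "cox")

    def test_cross_check_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        spec = GeneratorSpec(family="loglogistic", shape=1.5, scale=0.005,
                             n=1500, dropout_frac=0.2, seed=5)
        ref, _ = gen_survival(spec)
        t, e = ref.times, ref.events

        wf = lifelines.WeibullFitter().fit(t, e)
        ours = fit_parametric(ref, "weibull")
        # lifelines: S = exp(-(t/lambda)^rho); ours: exp(-scale t^shape)
        assert ours.shape == pytest.approx(wf.rho_, rel=1e-3)
        assert ours.scale == pytest.approx(wf.lambda_ ** -wf.rho_, rel=1e-3)
        assert ours.log_likelihood == pytest.approx(
            wf.log_likelihood_, abs=0.01)

        llf = lifelines.LogLogisticFitter().fit(t, e)
        ours = fit_parametric(ref, "loglogistic")
        # lifelines: S = 1/(1 + (t/alpha)^beta)
        assert ours.shape == pytest.approx(llf.beta_, rel=1e-3)
        assert ours.scale == pytest.approx(llf.alpha_ ** -llf.beta_, rel=1e-3)
        assert ours.log_likelihood == pytest.approx(
            llf.log_likelihood_, abs=0.01)

        lnf = lifelines.LogNormalFitter().fit(t, e)
        ours = fit_parametric(ref, "lognormal")
        assert ours.scale == pytest.approx(lnf.mu_, abs=1e-3)
        assert ours.shape == pytest.approx(lnf.sigma_, rel=1e-3)


class TestSelectBest:
    def test_argmin_aic(self):
        fits = [SurvivalFit("weibull", 1.0, 1.0, -153.1, 310.2, 2),
                SurvivalFit("loglogistic", 1.0, 1.0, -150.55, 305.1, 2),
                SurvivalFit("exponential", None, 1.0, -159.0, 320.0, 1)]
        assert select_best(fits).family == "loglogistic"

    def test_tie_prefers_fewer_parameters(self):
        one = SurvivalFit("exponential", None, 0.01, -100.0, 202.0, 1)
        two = SurvivalFit("weibull", 1.0, 0.01, -99.0, 202.0, 2)
        assert select_best([two, one]) is one

    def test_tie_prefers_family_order(self):
        a = SurvivalFit("lognormal", 1.0, 3.0, -99.0, 202.0, 2)
        b = SurvivalFit("weibull", 1.0, 0.01, -99.0, 202.0, 2)
        assert select_best([a, b]).family == "weibull"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_family_recovery_on_large_sample(self):
        spec = GeneratorSpec(family="loglogistic", shape=1.5, scale=0.005,
                             n=5000, dropout_frac=0.2, seed=17)
        ref, _ = gen_survival(spec)
        assert select_best(fit_all_families(ref)).family == "loglogistic"

    def test_fit_report_marks_selection(self):
        spec = GeneratorSpec(n=400, seed=9)
        ref, _ = gen_survival(spec)
        fits = fit_all_families(ref)
        rep = fit_report(fits)
        assert rep["selected"].sum() == 1
        assert set(rep["family"]) == set(FAMILIES)


class TestHazardRatio:
    def test_identity(self):
        fit = _fit("loglogistic", 1.5, 0.005)
        s = apply_hazard_ratio(fit, HazardRatio(1.0))
        grid = np.linspace(0, 500, 50)
        np.testing.assert_allclose(s(grid), survival_at(fit, grid), rtol=1e-15)

    def test_exponential_rate_doubling(self):
        s = apply_hazard_ratio(_fit("exponential", None, 0.01), 2.0)
        doubled = _fit("exponential", None, 0.02)
        grid = np.linspace(0, 300, 30)
        np.testing.assert_allclose(s(grid), survival_at(doubled, grid),
                                   rtol=1e-12)

    def test_loglogistic_square(self):
        s = apply_hazard_ratio(_fit("loglogistic", 1.0, 1.0), 2.0)
        assert s(1.0) == pytest.approx(0.25, rel=1e-12)

    @given(a=st.floats(0.2, 5.0), b=st.floats(0.2, 5.0),
           t=st.floats(0.0, 2000.0))
    def test_composition_multiplies(self, a, b, t):
        fit = _fit("loglogistic", 1.3, 7.7e-5)
        once = apply_hazard_ratio(apply_hazard_ratio(fit, a), b)
        direct = apply_hazard_ratio(fit, a * b)
        assert float(once(t)) == pytest.approx(float(direct(t)), rel=1e-10)

    def test_non_positive_hr_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(_fit("exponential", None, 0.01), 0.0)
        with pytest.raises(ValueError):
            HazardRatio(-1.0)


class TestPerCycleProbability:
    def test_exponential_is_memoryless(self):
        fit = _fit("exponential", None, 0.01)
        expected = 1.0 - math.exp(-0.01 * 28.0)
        for i in (0, 5, 100):
            assert per_cycle_progression_prob(fit, i, 28.0) == pytest.approx(
                expected, rel=1e-12)

    def test_loglogistic_first_cycle(self):
        fit = _fit("loglogistic", 1.0, 1.0)
        assert per_cycle_progression_prob(fit, 0, 1.0) == pytest.approx(0.5)

    def test_telescoping_identity(self):
        fit = _fit("loglogistic", 1.5, 0.005)
        probs = per_cycle_progression_probs(fit, 391, 28.0)
        prod = float(np.prod(1.0 - probs))
        assert prod == pytest.approx(survival_at(fit, 391 * 28.0), abs=1e-10)

    @given(scale=st.floats(1e-6, 1e-2), shape=st.floats(0.5, 2.5),
           n=st.integers(1, 120))
    def test_telescoping_property(self, scale, shape, n):
        fit = _fit("loglogistic", shape, scale)
        probs = per_cycle_progression_probs(fit, n, 28.0)
        assert np.all((0.0 <= probs) & (probs <= 1.0))
        assert float(np.prod(1.0 - probs)) == pytest.approx(
            survival_at(fit, n * 28.0), abs=1e-10)

    def test_zero_survival_at_cycle_start_raises(self):
        with pytest.raises(ZeroDivisionError):
            per_cycle_progression_prob(lambda t: 0.0, 1, 28.0)

    def test_bad_arguments_raise(self):
        fit = _fit("exponential", None, 0.01)
        with pytest.raises(ValueError):
            per_cycle_progression_prob(fit, -1, 28.0)
        with pytest.raises(ValueError):
            per_cycle_progression_prob(fit, 0, 0.0)
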