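"""Parametric survival laws: evaluation, stitching, and censored MLE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from psma_cua.survival import (FAMILIES, PiecewiseSurvival, SurvivalDistribution,
                               conditional_event_prob, fit_parametric, hazard,
                               rank_fits, stitch, survival)
from psma_cua.synthetic import simulate_ipd

# one representative valid parameter set per family
EXAMPLES = {
    "exponential": {"rate": 0.1},
    "weibull": {"shape": 1.4, "scale": 12.0},
    "gamma": {"shape": 1.6065, "rate": 0.1140},
    "lognormal": {"meanlog": 2.1048, "sdlog": 0.9841},
    "loglogistic": {"shape": 1.9263, "scale": 15.5377},
    "gompertz": {"shape": 0.05, "rate": 0.03},
    "gengamma": {"mu": 2.0, "sigma": 0.8, "Q": 0.7},
}


@pytest.mark.parametrize("family,params", EXAMPLES.items())
def test_survival_basic_shape(family, params):
    """S(0)=1, S in [0,1], and S non-increasing on a dense grid."""
    d = SurvivalDistribution(family, params)
    assert survival(d, 0.0) == pytest.approx(1.0)
    grid = np.linspace(0.0, 120.0, 601)
    s = survival(d, grid)
    assert np.all((s >= 0.0) & (s <= 1.0))
    assert np.all(np.diff(s) <= 1e-12)


def test_loglogistic_median_is_scale():
    # the published third-line PRLT OS law: median at the scale parameter,
    # close to the trial's reported 15.3-month median OS
    d = SurvivalDistribution("loglogistic", {"shape": 1.9263, "scale": 15.5377})
    assert survival(d, 15.5377) == pytest.approx(0.5, abs=1e-12)


def test_gamma_survival_matches_quadrature():
    """S(60) for the SoC OS gamma equals 1 minus the integrated density."""
    shape, rate = 1.6065, 0.1140
    d = SurvivalDistribution("gamma", {"shape": shape, "rate": rate})
    pdf = lambda t: stats.gamma.pdf(t, a=shape, scale=1 / rate)
    integral, err = integrate.quad(pdf, 0, 60, limit=200)
    assert survival(d, 60.0) == pytest.approx(1.0 - integral, abs=1e-8)


@pytest.mark.parametrize("family,params", EXAMPLES.items())
def test_hazard_matches_log_survival_slope(family, params):
    """h(t) = −d/dt ln S(t), checked by central finite differences."""
    d = SurvivalDistribution(family, params)
    t, h = 15.5377, 1e-5
    num = -(np.log(survival(d, t + h)) - np.log(survival(d, t - h))) / (2 * h)
    assert hazard(d, t) == pytest.approx(num, rel=1e-5)


def test_hazard_closed_forms():
    assert hazard(SurvivalDistribution("exponential", {"rate": 0.3}), 7.0) \
        == pytest.approx(0.3)
    assert hazard(SurvivalDistribution("weibull", {"shape": 1.0, "scale": 5.0}), 2.0) \
        == pytest.approx(0.2)


def test_conditional_event_prob():
    d = SurvivalDistribution("loglogistic", {"shape": 1.9263, "scale": 15.5377})
    assert conditional_event_prob(d, 3.0, 3.0) == 0.0
    e = SurvivalDistribution("exponential", {"rate": 0.07})
    assert conditional_event_prob(e, 4.0, 6.5) == pytest.approx(-math.expm1(-0.07 * 2.5))
    # direct evaluation oracle for the first model cycle
    expect = 1.0 - (1 / (1 + (1 / 15.5377) ** 1.9263))
    assert conditional_event_prob(d, 0.0, 1.0) == pytest.approx(expect, rel=1e-12)


@pytest.mark.parametrize("family,params", EXAMPLES.items())
def test_cycle_probs_consistent_with_survival(family, params):
    """Chained per-cycle survival reproduces S(T)/S(0) to 1e-10."""
    d = SurvivalDistribution(family, params)
    T = 24
    probs = [conditional_event_prob(d, c, c + 1) for c in range(T)]
    assert np.prod([1 - p for p in probs]) == pytest.approx(
        survival(d, T) / survival(d, 0), rel=1e-10)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError, match="shape"):
        SurvivalDistribution("weibull", {"shape": -1.0, "scale": 2.0})
    with pytest.raises(ValueError, match="family"):
        SurvivalDistribution("cauchy", {"x": 1.0})
    with pytest.raises(ValueError, match="expects parameters"):
        SurvivalDistribution("weibull", {"shape": 1.0})
    d = SurvivalDistribution("exponential", {"rate": 0.1})
    with pytest.raises(ValueError, match="t must be >= 0"):
        survival(d, -1.0)
    with pytest.raises(ValueError, match="t1 must be >= t0"):
        conditional_event_prob(d, 5.0, 4.0)


class TestStitch:
    def test_single_segment_passthrough(self):
        d = SurvivalDistribution("weibull", {"shape": 1.3, "scale": 9.0})
        assert stitch([d], []) is d

    def test_identical_exponentials_equal_plain(self):
        e = SurvivalDistribution("exponential", {"rate": 0.12})
        pw = stitch([e, e], [5.0])
        grid = np.linspace(0, 40, 161)
        np.testing.assert_allclose(pw.survival(grid), e.survival(grid), rtol=1e-12)

    def test_soc_pfs_continuity_at_knot(self):
        # third-line SoC PFS: log-logistic below 3.6 months, log-normal above
        pw = stitch(
            [SurvivalDistribution("loglogistic", {"shape": 4.7332, "scale": 2.3643}),
             SurvivalDistribution("lognormal", {"meanlog": 2.2763, "sdlog": 0.8268})],
            [3.6])
        left = pw.survival(3.6 - 1e-9)
        right = pw.survival(3.6 + 1e-9)
        assert abs(left - right) < 1e-6
        assert abs(pw.survival(3.6) - left) < 1e-6
        grid = np.linspace(0, 60, 601)
        s = pw.survival(grid)
        assert s[0] == 1.0 and np.all(np.diff(s) <= 1e-12)

    def test_cycle_spanning_knot_uses_stitched_survival(self):
        a = SurvivalDistribution("exponential", {"rate": 0.2})
        b = SurvivalDistribution("exponential", {"rate": 0.05})
        pw = stitch([a, b], [3.5])
        # S(4)/S(3) = exp(-0.2*0.5) * exp(-0.05*0.5)
        assert conditional_event_prob(pw, 3.0, 4.0) == pytest.approx(
            1 - math.exp(-0.2 * 0.5 - 0.05 * 0.5), rel=1e-12)

    def test_mismatched_segments_raise(self):
        e = SurvivalDistribution("exponential", {"rate": 0.1})
        with pytest.raises(ValueError):
            stitch([e], [2.0])


@given(shape=st.floats(0.5, 5.0), scale=st.floats(1.0, 40.0),
       t0=st.floats(0.0, 50.0), dt=st.floats(0.0, 10.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_conditional_prob_in_unit_interval(shape, scale, t0, dt):
    d = SurvivalDistribution("loglogistic", {"shape": shape, "scale": scale})
    p = conditional_event_prob(d, t0, t0 + dt)
    assert 0.0 <= p <= 1.0


@pytest.fixture(scope="module")
def exp_data():
    truth = SurvivalDistribution("exponential", {"rate": 0.1})
    ipd = simulate_ipd(truth, 5000, censor_at=None, seed=11)
    # ~20% uniform administrative censoring
    rng = np.random.default_rng(12)
    cens = rng.uniform(0, 75, size=5000)
    times = np.minimum(ipd.times, cens)
    events = (ipd.times <= cens).astype(int)
    return times, events


class TestFit:

    def test_exponential_recovery_within_3se(self, exp_data):
        fit = fit_parametric(exp_data, "exponential")
        assert fit.converged
        log_rate = fit.unconstrained_params[0]
        se = math.sqrt(fit.vcov[0, 0])
        assert abs(log_rate - math.log(0.1)) < 3 * se

    def test_weibull_nests_exponential(self, exp_data):
        fit = fit_parametric(exp_data, "weibull")
        i = fit.param_names.index("shape")
        se = math.sqrt(fit.vcov[i, i])
        assert abs(fit.unconstrained_params[i] - 0.0) < 3 * se

    def test_information_criteria_definitions(self, exp_data):
        fit = fit_parametric(exp_data, "weibull")
        assert fit.aic == pytest.approx(4 - 2 * fit.loglik)
        n = len(exp_data[0])
        assert fit.bic == pytest.approx(2 * math.log(n) - 2 * fit.loglik)

    def test_vcov_symmetric_psd(self, exp_data):
        fit = fit_parametric(exp_data, "weibull")
        np.testing.assert_allclose(fit.vcov, fit.vcov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-10)

    def test_loglik_cross_checked_against_lifelines(self):
        """Independent MLE route: lifelines' Weibull fitter on the same data."""
        from lifelines import WeibullFitter
        truth = SurvivalDistribution("weibull", {"shape": 1.4, "scale": 14.0})
        ipd = simulate_ipd(truth, 800, censor_at=30.0, seed=5)
        ours = fit_parametric(ipd, "weibull")
        wf = WeibullFitter().fit(ipd.times, ipd.events)
        # lifelines' lambda_ is our scale, rho_ our shape
        assert ours.distribution.params["scale"] == pytest.approx(wf.lambda_, rel=1e-3)
        assert ours.distribution.params["shape"] == pytest.approx(wf.rho_, rel=1e-3)
        assert ours.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_rank_fits_orders_by_aic(self):
        truth = SurvivalDistribution("lognormal", {"meanlog": 2.0, "sdlog": 0.6})
        ipd = simulate_ipd(truth, 600, censor_at=40.0, seed=9)
        fits = rank_fits(ipd, ["exponential", "weibull", "lognormal"])
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)
        assert fits[0].distribution.family == "lognormal"

    def test_too_few_events_raise(self):
        with pytest.raises(ValueError, match="events"):
            fit_parametric((np.array([1.0, 2.0]), np.array([0, 0])), "exponential")
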