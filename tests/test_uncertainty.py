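"""Observed information, Wald / boundary-mixture / profile intervals,
coverage estimation."""

import math

import numpy as np
import pytest
from scipy import stats

from doublecox import (ConfidenceInterval, DoubleCoxParams, FitOptions,
                       ModelSpec, SimulationConfig, coverage_probability,
                       draw_dataset, fit_ml, observed_information, profile_ci,
                       sigma2_boundary_ci, wald_ci)
from doublecox.estimation import _maximize, _pack
from doublecox.likelihood import LoglikData
from doublecox.uncertainty import (CHI2_95_1DF, mixture_cdf, mixture_quantile,
                                   numerical_hessian)

OPTS = FitOptions(multistart=1, seed=0)


class TestNumericalHessian:
    def test_exponential_information_is_event_count(self):
        """For an exponential model in the log-rate mu, l = d*mu - e^mu * R;
        the observed information at the MLE equals d exactly."""
        d, R = 37.0, 412.5
        mu_hat = math.log(d / R)

        def negloglik(x):
            return -(d * x[0] - math.exp(x[0]) * R)

        H = numerical_hessian(negloglik, np.array([mu_hat]))
        assert H[0, 0] == pytest.approx(d, rel=1e-6)

    def test_symmetric_output(self, gompertz_dataset, gompertz_fit):
        ds, spec = gompertz_dataset
        info = observed_information(ds, spec, gompertz_fit.params)
        assert np.max(np.abs(info.covariance - info.covariance.T)) < 1e-10

    def test_richardson_cross_check(self, gompertz_dataset, gompertz_fit):
        """Step-halving extrapolated Hessian agrees with the plain one."""
        ds, spec = gompertz_dataset
        plain = observed_information(ds, spec, gompertz_fit.params)
        rich = observed_information(ds, spec, gompertz_fit.params, richardson=True)
        rel = np.abs(plain.covariance - rich.covariance) / (np.abs(rich.covariance) + 1e-12)
        assert np.max(np.diag(rel)) < 1e-4


class TestWald:
    def test_halfwidth_is_z_times_se(self, gompertz_dataset, gompertz_fit):
        ds, spec = gompertz_dataset
        info = observed_information(ds, spec, gompertz_fit.params)
        cis = {ci.parameter: ci for ci in wald_ci(gompertz_fit, info, 0.95)}
        z = stats.norm.ppf(0.975)
        ci = cis["beta_scale_Success"]
        est = gompertz_fit.params.beta_scale[0]
        assert ci.upper - est == pytest.approx(z * info.se("beta_scale_Success"), rel=1e-10)
        assert est - ci.lower == pytest.approx(z * info.se("beta_scale_Success"), rel=1e-10)

    def test_baseline_scale_interval_asymmetric(self, gompertz_dataset, gompertz_fit):
        ds, spec = gompertz_dataset
        info = observed_information(ds, spec, gompertz_fit.params)
        ci = next(c for c in wald_ci(gompertz_fit, info) if c.parameter == "a")
        a = gompertz_fit.params.a
        assert ci.lower < a < ci.upper
        # exponentiated interval: upper gap strictly exceeds lower gap
        assert (ci.upper - a) > (a - ci.lower)


class TestBoundaryMixture:
    def test_cdf_quantile_inverse_pair(self):
        nu, kappa = 2.3, 1.7
        for p in np.linspace(0.01, 0.99, 25):
            q = mixture_quantile(p, nu, kappa)
            if q > 0:
                assert mixture_cdf(q, nu, kappa) == pytest.approx(p, abs=1e-10)
            else:
                # inside the atom at zero: CDF at 0 covers p
                assert mixture_cdf(0.0, nu, kappa) >= p

    def test_cdf_total_mass(self):
        assert mixture_cdf(1e8, 1.0, 2.0) == pytest.approx(1.0, abs=1e-12)
        assert mixture_cdf(-0.1, 1.0, 2.0) == 0.0

    def test_quantiles_match_monte_carlo(self):
        """1e6 draws from the mixture reproduce the closed-form quantiles."""
        nu, kappa = 0.8, 1.1
        rng = np.random.default_rng(0)
        n = 1_000_000
        # the mixture is the law of max(N(nu, kappa^2), 0): the negative mass
        # collapses into the atom at zero, the rest is the truncated normal
        draws = np.maximum(rng.normal(nu, kappa, n), 0.0)
        for p in (0.025, 0.5, 0.975):
            assert mixture_quantile(p, nu, kappa) == pytest.approx(
                np.quantile(draws, p), abs=1e-3 + 3e-3 * kappa)

    def test_boundary_estimate_gives_zero_lower(self, gompertz_dataset):
        ds, spec = gompertz_dataset
        import dataclasses
        fit = fit_ml(ds, spec, OPTS)
        info = observed_information(ds, spec, fit.params)
        fit_zero = dataclasses.replace(fit, params=fit.params.replace(sigma2=0.0))
        ci = sigma2_boundary_ci(fit_zero, info)
        assert ci.lower == 0.0
        assert ci.method == "boundary_mixture"
        # half the mixture mass sits in the atom at zero when nu = 0
        assert mixture_cdf(0.0, 0.0, info.kappa) == pytest.approx(0.5)

    def test_far_from_boundary_matches_wald(self, gompertz_dataset, gompertz_fit):
        """When sigma2_hat is many SEs above 0 the mixture interval is the
        plain normal interval."""
        ds, spec = gompertz_dataset
        info = observed_information(ds, spec, gompertz_fit.params)
        ci = sigma2_boundary_ci(gompertz_fit, info)
        se = info.se("sigma2")
        s2 = gompertz_fit.params.sigma2
        if s2 / se > 3:
            z = stats.norm.ppf(0.975)
            assert ci.lower == pytest.approx(s2 - z * se, rel=1e-6)
            assert ci.upper == pytest.approx(s2 + z * se, rel=1e-6)


class TestProfile:
    def test_chi2_inversion_constant(self):
        assert CHI2_95_1DF == pytest.approx(3.84, abs=0.005)

    def test_mle_inside_own_interval(self, gompertz_dataset, gompertz_fit):
        ds, spec = gompertz_dataset
        ci = profile_ci(ds, spec, gompertz_fit, "beta_scale_Score")
        assert ci.contains(gompertz_fit.params.beta_scale[1])

    def test_endpoints_satisfy_defining_equation(self, gompertz_dataset, gompertz_fit):
        """2*(l_max - l_profile(endpoint)) == chi2 threshold to 1e-3."""
        ds, spec = gompertz_dataset
        target = "beta_scale_Success"
        ci = profile_ci(ds, spec, gompertz_fit, target)
        data = LoglikData(ds, spec)
        idx = spec.parameter_names().index(target)
        for v in (ci.lower, ci.upper):
            x0 = _pack(gompertz_fit.params, True)
            x0[idx] = v
            _, lp, *_ = _maximize(data, x0, 2, 2, True,
                                  FitOptions(multistart=1, gradient_tolerance=1e-9),
                                  fixed={idx: v})
            assert 2.0 * (gompertz_fit.loglik - lp) == pytest.approx(
                CHI2_95_1DF, abs=1e-3)

    def test_sigma2_profile_respects_boundary(self):
        """Weak-frailty data: the sigma2 profile interval must not cross 0."""
        truth = DoubleCoxParams(a=20.0, b=1.5, beta_scale=[0.5, 1.0], sigma2=0.05)
        cfg = SimulationConfig(family="weibull", truth=truth, N=400, Ncl=40,
                               p_cens=0.0, p_Success=0.5, seed=77)
        ds = draw_dataset(cfg)
        fit = fit_ml(ds, cfg.model_spec(), OPTS)
        ci = profile_ci(ds, cfg.model_spec(), fit, "sigma2")
        assert ci.lower >= 0.0
        assert ci.contains(fit.params.sigma2)

    def test_wald_profile_agree_at_large_n(self, weibull_truth):
        """Quadratic-likelihood limit: interval widths within 5% at N=1e4."""
        cfg = SimulationConfig(family="weibull", truth=weibull_truth, N=10_000,
                               Ncl=100, p_cens=0.0, p_Success=0.25, seed=19)
        ds = draw_dataset(cfg)
        spec = cfg.model_spec()
        fit = fit_ml(ds, spec, OPTS)
        info = observed_information(ds, spec, fit.params)
        wald = {c.parameter: c for c in wald_ci(fit, info)}
        prof = profile_ci(ds, spec, fit, "beta_scale_Success")
        w_width = wald["beta_scale_Success"].upper - wald["beta_scale_Success"].lower
        p_width = prof.upper - prof.lower
        assert abs(p_width - w_width) / w_width < 0.05


class TestCoverage:
    def test_everything_and_nothing(self):
        inf_ci = [ConfidenceInterval("x", -math.inf, math.inf, 0.95, "wald")
                  for _ in range(7)]
        assert coverage_probability(inf_ci, 3.3).value == 1.0
        miss = [ConfidenceInterval("x", 0.0, 1.0, 0.95, "wald") for _ in range(7)]
        assert coverage_probability(miss, 5.0).value == 0.0

    def test_normal_mean_textbook_sanity(self):
        """95% z-intervals for a normal mean cover about 95% of the time."""
        rng = np.random.default_rng(12)
        z = stats.norm.ppf(0.975)
        n, reps = 30, 2000
        intervals = []
        for _ in range(reps):
            x = rng.normal(0.0, 1.0, n)
            m = x.mean()
            half = z / math.sqrt(n)
            intervals.append(ConfidenceInterval("mu", m - half, m + half, 0.95, "wald"))
        cov = coverage_probability(intervals, 0.0)
        assert cov.value == pytest.approx(0.95, abs=3 * cov.se + 0.005)
        assert cov.se == pytest.approx(math.sqrt(cov.value * (1 - cov.value) / reps))
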