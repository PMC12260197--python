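import math

import numpy as np
import pytest
from scipy import stats

from extrapsim import distributions as dist
from extrapsim.fitting import (FitResult, SelectionFailure, aicc, bic,
                               draw_parameters, fit_all_families, fit_excess,
                               fit_parametric, select_best)
from extrapsim.mortality import MortalityLaw, cumulative_hazard, \
    sample_death_time, zero_law


def exp_sample(rate, n, seed, censor_at=None):
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, size=n)
    if censor_at is None:
        return t, np.ones(n, dtype=bool)
    return np.minimum(t, censor_at), t <= censor_at


class TestNaiveMLE:
    def test_exponential_mle_equals_closed_form(self):
        t, e = exp_sample(0.5, 400, 1, censor_at=3.0)
        fit = fit_parametric(t, e, "exponential")
        assert fit.converged
        assert fit.params["rate"] == pytest.approx(e.sum() / t.sum(), rel=1e-5)

    def test_exponential_recovery_uncensored(self):
        t, e = exp_sample(0.5, 5000, 2)
        fit = fit_parametric(t, e, "exponential")
        assert 0.48 <= fit.params["rate"] <= 0.52

    def test_weibull_recovery(self, rng):
        t = 2.0 * rng.weibull(1.6, size=5000)
        fit = fit_parametric(t, np.ones_like(t, dtype=bool), "weibull")
        assert fit.params["shape"] == pytest.approx(1.6, rel=0.04)
        assert fit.params["scale"] == pytest.approx(2.0, rel=0.04)

    def test_gompertz_recovery(self, rng):
        law = MortalityLaw("gompertz", {"rate": 0.2, "shape": 0.3}, x0=0.0)
        t = np.asarray(sample_death_time(law, 0.0, rng.uniform(1e-12, 1, 5000)))
        fit = fit_parametric(t, np.ones_like(t, dtype=bool), "gompertz")
        assert fit.params["rate"] == pytest.approx(0.2, rel=0.04)
        assert fit.params["shape"] == pytest.approx(0.3, rel=0.04)

    def test_underidentified_fit_flags_not_converged(self):
        fit = fit_parametric(np.array([1.0]), np.array([True]), "gengamma")
        assert not fit.converged
        assert fit.params is None

    def test_no_events_is_failure_not_exception(self):
        fit = fit_parametric(np.ones(10), np.zeros(10, dtype=bool), "exponential")
        assert not fit.converged

    def test_nested_families_increase_loglik(self):
        t, e = exp_sample(0.4, 300, 3, censor_at=5.0)
        lls = [fit_parametric(t, e, fam).loglik
               for fam in ("exponential", "weibull", "gengamma")]
        assert lls[0] <= lls[1] + 1e-6
        assert lls[1] <= lls[2] + 1e-4


class TestExcessMLE:
    def test_zero_background_equals_naive(self):
        t, e = exp_sample(0.5, 500, 4, censor_at=4.0)
        for fam in ("exponential", "weibull", "lognormal"):
            naive = fit_parametric(t, e, fam)
            excess = fit_excess(t, e, fam, zero_law(), age0=60.0)
            assert excess.loglik == pytest.approx(naive.loglik, abs=1e-6)

    def test_excess_rate_recovery_under_gompertz_background(self, rng):
        law = MortalityLaw("gompertz", {"rate": 0.02, "shape": 0.1}, x0=60.0)
        n = 5000
        t_bg = np.asarray(sample_death_time(law, 60.0, rng.uniform(1e-12, 1, n)))
        t_ex = rng.exponential(1.0 / 0.2, size=n)
        t = np.minimum(t_bg, t_ex)
        fit = fit_excess(t, np.ones(n, dtype=bool), "exponential", law, age0=60.0)
        assert 0.19 <= fit.params["rate"] <= 0.21

    def test_all_censored_excess_fails(self):
        law = MortalityLaw("gompertz", {"rate": 0.02, "shape": 0.1}, x0=60.0)
        fit = fit_excess(np.ones(20), np.zeros(20, dtype=bool), "exponential",
                         law, age0=60.0)
        assert not fit.converged

    def test_per_subject_age_vector_accepted(self, rng):
        law = MortalityLaw("gompertz", {"rate": 0.02, "shape": 0.1}, x0=60.0)
        t, e = exp_sample(0.3, 200, 5, censor_at=4.0)
        ages = rng.uniform(60, 70, size=200)
        fit = fit_excess(t, e, "exponential", law, age0=ages)
        assert fit.converged


class TestInformationCriteria:
    def test_aicc_arithmetic(self):
        assert aicc(-50.0, 2, 30) == pytest.approx(104 + 12 / 27)

    def test_aicc_tends_to_aic(self):
        assert aicc(-50.0, 2, 10**7) == pytest.approx(104.0, abs=1e-4)

    def test_small_n_ineligible(self):
        assert aicc(-1.0, 3, 4) == math.inf

    def test_bic_formula(self):
        assert bic(-50.0, 2, 30) == pytest.approx(100 + 2 * math.log(30))


class TestSelection:
    def _fit(self, family, aicc_val, converged=True):
        return FitResult(family=family, aicc=aicc_val, converged=converged,
                         params={}, loglik=0.0)

    def test_lowest_aicc_wins(self):
        fits = [self._fit("weibull", 104.4), self._fit("lognormal", 103.9),
                self._fit("gompertz", None, converged=False)]
        assert select_best(fits).family == "lognormal"

    def test_all_failed_raises(self):
        with pytest.raises(SelectionFailure):
            select_best([self._fit("weibull", None, converged=False)])

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._fit("gengamma", 100.0), self._fit("weibull", 100.0)]
        assert select_best(fits).family == "weibull"

    def test_fit_all_families_covers_six(self):
        t, e = exp_sample(0.5, 300, 6, censor_at=4.0)
        fits = fit_all_families(t, e)
        assert [f.family for f in fits] == list(dist.FAMILIES)
        best = select_best(fits)
        assert best.converged


class TestDrawParameters:
    def test_zero_covariance_returns_mle(self):
        fit = FitResult(family="weibull", params={"shape": 1.5, "scale": 2.0},
                        cov=np.zeros((2, 2)), converged=True)
        draws = draw_parameters(fit, 5, seed=0)
        np.testing.assert_allclose(draws["shape"], 1.5)
        np.testing.assert_allclose(draws["scale"], 2.0)

    def test_seeded_determinism(self):
        t, e = exp_sample(0.5, 200, 7)
        fit = fit_parametric(t, e, "exponential")
        a = draw_parameters(fit, 50, seed=3)
        b = draw_parameters(fit, 50, seed=3)
        np.testing.assert_array_equal(a["rate"], b["rate"])

    def test_draw_mean_near_mle(self):
        t, e = exp_sample(0.5, 500, 8)
        fit = fit_parametric(t, e, "exponential")
        draws = draw_parameters(fit, 10_000, seed=1)
        log_mean = np.mean(np.log(draws["rate"]))
        se = math.sqrt(fit.cov[0, 0])
        assert abs(log_mean - math.log(fit.params["rate"])) < 3 * se / 100

    def test_estimation_scale_ellipsoid_coverage(self):
        # 95% Wald interval for log-rate over repeated exponential refits
        hits = 0
        n_rep = 500
        rng = np.random.default_rng(44)
        for _ in range(n_rep):
            t = rng.exponential(2.0, size=500)
            fit = fit_parametric(t, np.ones_like(t, dtype=bool), "exponential")
            z = (math.log(fit.params["rate"]) - math.log(0.5)) ** 2 / fit.cov[0, 0]
            hits += z <= stats.chi2.ppf(0.95, 1)
        assert 0.92 <= hits / n_rep <= 0.98


class TestEvalFunctions:
    def test_weibull_rate_form_point(self):
        # S(2) = e^-1 for shape 1.6, rate 0.5 (scale 2)
        from extrapsim.fitting import survival_eval
        s = survival_eval("weibull", {"shape": 1.6, "scale": 2.0}, 2.0)
        assert s == pytest.approx(math.exp(-1.0))

    def test_loglogistic_median_at_scale(self):
        from extrapsim.fitting import survival_eval
        s = survival_eval("loglogistic", {"shape": 1.7, "scale": 3.3}, 3.3)
        assert s == pytest.approx(0.5)

    def test_gengamma_special_cases_on_grid(self):
        t = np.linspace(0.05, 15, 200)
        wb = dist.survival("weibull", {"shape": 1.6, "scale": 2.0}, t)
        gg1 = dist.survival("gengamma",
                            {"mu": math.log(2.0), "sigma": 1 / 1.6, "q": 1.0}, t)
        assert np.max(np.abs(wb - gg1)) < 1e-10
        ln = dist.survival("lognormal", {"mu": 0.4, "sigma": 0.9}, t)
        gg0 = dist.survival("gengamma", {"mu": 0.4, "sigma": 0.9, "q": 0.0}, t)
        assert np.max(np.abs(ln - gg0)) < 1e-10

    def test_negative_time_rejected(self):
        from extrapsim.fitting import hazard_eval
        with pytest.raises(ValueError):
            hazard_eval("exponential", {"rate": 1.0}, -1.0)

    @pytest.mark.parametrize("family, params", [
        ("exponential", {"rate": 0.7}),
        ("weibull", {"shape": 0.6, "scale": 3.0}),
        ("gompertz", {"rate": 0.1, "shape": 0.2}),
        ("lognormal", {"mu": 0.5, "sigma": 1.1}),
        ("loglogistic", {"shape": 2.0, "scale": 1.5}),
        ("gengamma", {"mu": 0.2, "sigma": 0.8, "q": -0.7}),
    ])
    def test_survival_quantile_round_trip(self, family, params):
        p = np.array([0.95, 0.5, 0.1, 0.01])
        t = dist.inverse_survival(family, params, p)
        np.testing.assert_allclose(dist.survival(family, params, t), p,
                                   rtol=1e-8)
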