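import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from extrapsim.fitting import FitResult
from extrapsim.mortality import MortalityLaw, zero_law
from extrapsim.msm import (ModelFailure, Transition, TransitionMatrix,
                           build_transition_matrix, run_msm, simulate_sojourns)
from extrapsim.psm import integrate_means, psm_occupancy


def exp_fit(rate, cov=0.0, mode="naive"):
    return FitResult(family="exponential", params={"rate": rate},
                     cov=np.array([[cov]]), converged=True, loglik=0.0,
                     aicc=0.0, mode=mode)


def failed_fit():
    return FitResult(family="exponential", converged=False)


def toy_matrix(prog=0.5, death=0.2):
    """3-transition toy: PF->PD and PD->death, no background mortality."""
    return TransitionMatrix("msm_gpm_4_fallback", [
        Transition("PF", "PD", "fitted", "state-entry", fit=exp_fit(prog)),
        Transition("PF", "death", "background", "age", law=zero_law()),
        Transition("PD", "death", "background", "age", law=zero_law()),
        Transition("PD", "death", "fitted", "state-entry", fit=exp_fit(death)),
    ])


def phase_type_oracle(prog, death, horizon):
    """Restricted mean PF/PD occupancy by numeric ODE integration."""
    def rhs(t, y):
        p_pf, p_pd, int_pf, int_pd = y
        return [-prog * p_pf, prog * p_pf - death * p_pd, p_pf, p_pd]
    sol = solve_ivp(rhs, (0, horizon), [1.0, 0.0, 0.0, 0.0],
                    rtol=1e-10, atol=1e-12)
    return sol.y[2, -1], sol.y[3, -1]


class TestBuildTransitionMatrix:
    def test_full_gpm_matrix_has_five_transitions(self):
        m = build_transition_matrix(exp_fit(0.5), exp_fit(0.2, mode="excess"),
                                    zero_law(), "msm_gpm",
                                    pf_death_excess_fit=exp_fit(0.01, mode="excess"))
        assert m.variant == "msm_gpm_5"
        assert len(m.transitions) == 5

    def test_missing_pf_death_excess_falls_back_to_four(self):
        m = build_transition_matrix(exp_fit(0.5), exp_fit(0.2, mode="excess"),
                                    zero_law(), "msm_gpm",
                                    pf_death_excess_fit=failed_fit())
        assert m.variant == "msm_gpm_4_fallback"
        assert len(m.transitions) == 4

    def test_partly_naive_matrix(self):
        m = build_transition_matrix(exp_fit(0.5), exp_fit(0.2, mode="excess"),
                                    zero_law(), "msm_partly_naive",
                                    pf_death_naive_fit=exp_fit(0.05))
        assert m.variant == "partly_naive_4"
        sources = [(t.from_state, t.source) for t in m.transitions]
        assert ("PF", "background") not in sources

    def test_required_component_failure_raises(self):
        with pytest.raises(ModelFailure):
            build_transition_matrix(failed_fit(), exp_fit(0.2), zero_law())
        with pytest.raises(ModelFailure):
            build_transition_matrix(exp_fit(0.5), failed_fit(), zero_law())


class TestSimulateSojourns:
    def test_single_transition_restricted_mean(self):
        m = TransitionMatrix("toy", [
            Transition("PF", "death", "fitted", "state-entry", fit=exp_fit(0.5))])
        pf, pd_, os_ = simulate_sojourns(m, horizon=22.0, n_individuals=200_000,
                                         seed=0)
        expected = (1 - math.exp(-11.0)) / 0.5
        assert pd_ == 0.0
        assert os_ == pytest.approx(expected, abs=3 * 2.0 / math.sqrt(200_000))

    def test_all_exponential_toy_matches_ode_oracle(self):
        n = 100_000
        pf, pd_, os_ = simulate_sojourns(toy_matrix(), horizon=22.0,
                                         n_individuals=n, seed=1)
        pf_true, pd_true = phase_type_oracle(0.5, 0.2, 22.0)
        # 3 monte-carlo standard errors (sojourn sds ~2 and ~4.4 years)
        assert pf == pytest.approx(pf_true, abs=3 * 2.0 / math.sqrt(n))
        assert pd_ == pytest.approx(pd_true, abs=3 * 4.4 / math.sqrt(n))
        assert os_ == pytest.approx(pf + pd_, abs=1e-12)

    def test_zero_horizon_gives_zero_sojourns(self):
        assert simulate_sojourns(toy_matrix(), horizon=0.0) == (0.0, 0.0, 0.0)

    def test_first_event_wins_reproduces_additive_hazard(self):
        # two competing exponential PF exits: total PF-exit hazard 0.7
        m = TransitionMatrix("toy", [
            Transition("PF", "PD", "fitted", "state-entry", fit=exp_fit(0.5)),
            Transition("PF", "death", "fitted", "state-entry", fit=exp_fit(0.2)),
            Transition("PD", "death", "fitted", "state-entry", fit=exp_fit(10.0)),
        ])
        n = 100_000
        pf, _, _ = simulate_sojourns(m, horizon=50.0, n_individuals=n, seed=2)
        assert pf == pytest.approx(1 / 0.7, abs=3 * (1 / 0.7) / math.sqrt(n))

    def test_background_age_clock_advances_with_progression(self):
        # steep Gompertz background: PD mortality much higher when entered later
        law = MortalityLaw("gompertz", {"rate": 0.05, "shape": 0.15}, x0=60.0)
        slow = TransitionMatrix("toy", [
            Transition("PF", "PD", "fitted", "state-entry", fit=exp_fit(0.05)),
            Transition("PD", "death", "background", "age", law=law)])
        fast = TransitionMatrix("toy", [
            Transition("PF", "PD", "fitted", "state-entry", fit=exp_fit(5.0)),
            Transition("PD", "death", "background", "age", law=law)])
        _, pd_slow, _ = simulate_sojourns(slow, 60.0, 30_000, seed=3)
        _, pd_fast, _ = simulate_sojourns(fast, 60.0, 30_000, seed=3)
        assert pd_fast > pd_slow  # fast progressors spend most of life in PD


class TestRunMsm:
    def test_psa_zero_covariance_ci_reflects_first_order_noise_only(self):
        m = toy_matrix()
        est_small = run_msm(m, horizon=22.0, n_individuals=500, n_psa=40, seed=4)
        est_big = run_msm(m, horizon=22.0, n_individuals=8000, n_psa=40, seed=4)
        w = lambda e: e.ci["OS"][1] - e.ci["OS"][0]
        assert w(est_big) < w(est_small)
        assert w(est_big) < 3 * w(est_small) * math.sqrt(500 / 8000)

    def test_seeded_determinism(self):
        m = toy_matrix()
        a = run_msm(m, horizon=22.0, n_individuals=1000, n_psa=10, seed=9)
        b = run_msm(m, horizon=22.0, n_individuals=1000, n_psa=10, seed=9)
        assert a.os == b.os and a.ci == b.ci

    def test_os_identity_and_bounds(self):
        est = run_msm(toy_matrix(), horizon=22.0, n_individuals=2000,
                      n_psa=20, seed=5)
        assert est.os == pytest.approx(est.pf + est.pd, abs=1e-9)
        assert 0 <= est.pf <= 22 and 0 <= est.os <= 22


class TestEngineAgreement:
    def test_psm_and_msm_agree_on_true_scenario1_hazards(self):
        """Both engines fed the same true hazards estimate the same OS.

        PSM gets the true PFS curve and the analytic hypoexponential OS
        curve; the MSM simulates the same two transitions by DES.
        """
        prog, death, horizon = 0.5, 0.2, 22.0
        t = np.arange(0, horizon + 1e-9, 1 / 12)
        s_pfs = np.exp(-prog * t)
        s_os = (prog * np.exp(-death * t) - death * np.exp(-prog * t)) / (prog - death)
        occ = {"t": t, "pf": np.minimum(s_pfs, s_os),
               "pd": s_os - np.minimum(s_pfs, s_os)}
        pf_psm, pd_psm, os_psm = integrate_means(occ)
        pf_msm, pd_msm, os_msm = simulate_sojourns(
            toy_matrix(prog, death), horizon, n_individuals=100_000, seed=6)
        assert os_msm == pytest.approx(os_psm, rel=0.01)
        assert pf_msm == pytest.approx(pf_psm, rel=0.01)

    def test_matrix_json_description(self):
        m = toy_matrix()
        text = m.to_json()
        assert "msm_gpm_4_fallback" in text and "PF" in text
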