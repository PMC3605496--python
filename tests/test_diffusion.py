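"""Diffusion approximation: moments, Siegert rate, model fitting, sweeps."""

import numpy as np
import pytest

from synfire import NeuronParams
from synfire.diffusion import (
    GaussianMoments,
    effective_jump_E,
    fit_current_to_conductance,
    moments_conductance,
    moments_current,
    n_E_min_gaussian,
    siegert_rate,
    sweep_comparison,
)

from oracles import event_driven_lif, poisson_event_times


@pytest.fixture
def cond():
    return NeuronParams()


class TestMoments:
    def test_zero_input_rests_at_leak_equilibrium(self, cond):
        m = moments_conductance(0.0, 0.0, cond)
        assert m.mu == pytest.approx(cond.V_P)
        assert m.tau == pytest.approx(cond.tau_P)
        assert m.sigma == 0.0

    def test_effective_time_constant_printed_value(self, cond):
        # 1/tau = 1/20 + 1*(0.005 + 0.25*0.11) = 0.0825/ms at 1 kHz
        m = moments_conductance(1.0, 0.25, cond)
        assert 1.0 / m.tau == pytest.approx(0.0825)
        assert m.tau == pytest.approx(12.12, abs=0.01)

    def test_tau_decreases_with_background(self, cond):
        taus = [moments_conductance(lam, 0.25 * lam, cond).tau for lam in (0, 1, 10, 100)]
        assert taus[0] == pytest.approx(cond.tau_P)
        assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_current_moments_match_threshold_free_ensemble(self):
        """Brute-force ensemble of the current-based equation without a
        threshold reproduces the analytic (mu, sigma)."""
        p = NeuronParams(
            model_kind="current", a_E=0.2, a_I=-0.3, V_Theta=1e6, V_R=-70.0
        )
        lam_E, lam_I = 20.0, 5.0
        m = moments_current(lam_E, lam_I, p)
        rng = np.random.default_rng(8)
        finals = []
        for _ in range(400):
            exc = poisson_event_times(lam_E, 400.0, rng)
            inh = poisson_event_times(lam_I, 400.0, rng)
            _, v = event_driven_lif(p, exc, inh, 400.0, sample_times=[250.0, 399.0])
            finals.extend(v)
        finals = np.asarray(finals)
        assert finals.mean() == pytest.approx(m.mu, abs=4 * m.sigma / np.sqrt(len(finals) / 2))
        assert finals.std() == pytest.approx(m.sigma, rel=0.1)


class TestSiegertRate:
    def test_deep_subthreshold_is_negligible(self, cond):
        rate = siegert_rate(GaussianMoments(mu=-70.0, sigma=0.5, tau=20.0), cond)
        assert 0.0 <= rate < 1e-6

    def test_monotone_in_mean_and_spread(self, cond):
        rates_mu = [
            siegert_rate(GaussianMoments(mu, 2.0, 5.0), cond)
            for mu in (-70.0, -66.0, -62.0, -58.0)
        ]
        assert all(a < b for a, b in zip(rates_mu, rates_mu[1:]))
        rates_sigma = [
            siegert_rate(GaussianMoments(-68.0, s, 5.0), cond)
            for s in (1.0, 2.0, 3.0, 4.0)
        ]
        assert all(a < b for a, b in zip(rates_sigma, rates_sigma[1:]))

    def test_depends_only_on_moments_not_model_kind(self, cond):
        m = GaussianMoments(-62.0, 2.5, 3.0)
        cur = cond.replace(model_kind="current", a_E=0.3, a_I=-0.3, g_E=0, g_I=0)
        assert siegert_rate(m, cond) == pytest.approx(siegert_rate(m, cur))

    def test_nonpositive_sigma_rejected(self, cond):
        with pytest.raises(ValueError):
            siegert_rate(GaussianMoments(-65.0, 0.0, 5.0), cond)

    def test_agrees_with_monte_carlo_for_weak_current_synapses(self):
        """In the weak-synapse diffusion regime the first-passage formula
        matches event-driven simulation within 15 %."""
        p = NeuronParams(model_kind="current", a_E=0.1, a_I=-0.1, tau_ref=2.0)
        lam_E, lam_I = 160.0, 144.0  # mu = -62, sigma^2 = 10*(1.6+1.44)
        m = moments_current(lam_E, lam_I, p)
        analytic = siegert_rate(m, p)
        rng = np.random.default_rng(17)
        count, total_s = 0, 0.0
        for _ in range(30):
            exc = poisson_event_times(lam_E, 1200.0, rng)
            inh = poisson_event_times(lam_I, 1200.0, rng)
            spikes, _ = event_driven_lif(p, exc, inh, 1200.0)
            count += np.count_nonzero(spikes >= 200.0)
            total_s += 1.0
        mc = count / total_s
        assert mc > 0
        assert analytic == pytest.approx(mc, rel=0.15)


class TestPoolSizeCriterion:
    def test_worked_arithmetic(self, cond):
        n = n_E_min_gaussian(GaussianMoments(-65.0, 2.0, 5.0), cond, a_eff=0.3125)
        assert n == int(np.ceil((10 + 1.645 * 2.0) / 0.3125)) == 43

    def test_degenerate_at_threshold(self, cond):
        assert n_E_min_gaussian(GaussianMoments(cond.V_Theta, 0.0, 5.0), cond) == 0

    def test_monotone_in_spread(self, cond):
        ns = [
            n_E_min_gaussian(GaussianMoments(-65.0, s, 5.0), cond)
            for s in (0.5, 1.5, 2.5, 3.5)
        ]
        assert all(a <= b for a, b in zip(ns, ns[1:])) and ns[0] < ns[-1]

    def test_conductance_effective_jump(self, cond):
        # g_E (V_E - (V_R+V_Theta)/2) = 0.005 * 62.5
        assert effective_jump_E(cond) == pytest.approx(0.3125)
        assert round(effective_jump_E(cond), 3) == pytest.approx(0.312)

    def test_nonpositive_jump_rejected(self, cond):
        with pytest.raises(ValueError):
            n_E_min_gaussian(GaussianMoments(-65.0, 1.0, 5.0), cond, a_eff=0.0)


class TestFitCurrentToConductance:
    def test_fit_reproduces_target_moments(self, cond):
        fitted = fit_current_to_conductance(cond, C_E_fit=6000.0, nu=5.0)
        lam_E = 6000.0 * 5.0 / 1000.0
        target = moments_conductance(lam_E, 0.25 * lam_E, cond)
        got = moments_current(lam_E, 0.25 * lam_E, fitted)
        assert got.mu == pytest.approx(target.mu, abs=1e-9)
        assert got.sigma == pytest.approx(target.sigma, abs=1e-9)
        assert fitted.tau_P == pytest.approx(target.tau)

    def test_balanced_choice_zeroes_mean_drive(self, cond):
        fitted = fit_current_to_conductance(cond, C_E_fit=6000.0, nu=5.0)
        lam_E = 6000.0 * 5.0 / 1000.0
        assert fitted.a_E * lam_E + fitted.a_I * 0.25 * lam_E == pytest.approx(0.0, abs=1e-12)

    def test_rest_choice_trades_excitation_against_inhibition(self, cond):
        lam_E = 6000.0 * 5.0 / 1000.0
        target = moments_conductance(lam_E, 0.25 * lam_E, cond)
        ratios = []
        for V_P in (target.mu - 6.0, target.mu, target.mu + 6.0):
            f = fit_current_to_conductance(cond, 6000.0, 5.0, V_P_choice=V_P)
            ratios.append(f.a_E / abs(f.a_I))
        assert ratios[0] > ratios[1] > ratios[2]

    def test_extreme_rest_choice_infeasible(self, cond):
        with pytest.raises(ValueError, match="infeasible"):
            fit_current_to_conductance(cond, 6000.0, 5.0, V_P_choice=300.0)


class TestSweepComparison:
    def test_conductance_capacity_linear_at_strong_inhibition(self):
        """With strong inhibition the conductance model's minimum pool size
        saturates, so capacity grows essentially linearly in connectivity."""
        sweep = sweep_comparison("conductance", varied_grid=[0.10])
        s = sweep.series[0]
        assert s.C_E.size >= 8
        half = s.C_E.size // 2
        r = np.corrcoef(s.C_E[half:], s.alpha_max[half:])[0, 1]
        assert r > 0.999
        assert np.ptp(s.n_E_min[half:]) <= 2

    def test_conventional_current_capacity_decreases_with_inhibition(self):
        # fine connectivity grid: the optimum sits at low C_E for this family
        sweep = sweep_comparison(
            "current", varied_grid=[0.5, 1.0, 1.5],
            C_E_grid=np.arange(50.0, 20001.0, 50.0),
        )
        best = [s.alpha_max.max() for s in sweep.series if s.alpha_max.size]
        assert len(best) == 3
        assert all(a > b for a, b in zip(best, best[1:]))

    def test_both_termination_conditions_occur(self):
        """The stochastic-rate bound truncates the conductance family while
        the instability bound truncates the balanced fitted family."""
        cond_sweep = sweep_comparison("conductance", varied_grid=[0.08, 0.095])
        fit_sweep = sweep_comparison("fitted_gi", varied_grid=[0.08, 0.095])
        cond_terms = {s.terminating_condition for s in cond_sweep.series}
        fit_terms = {s.terminating_condition for s in fit_sweep.series}
        assert "nu_S_bound" in cond_terms
        assert "instability" in fit_terms

    def test_fitted_vp_family_runs(self):
        sweep = sweep_comparison("fitted_vp", varied_grid=[-75.0, -65.0])
        assert len(sweep.series) == 2
        for s in sweep.series:
            assert s.C_E.size > 0
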