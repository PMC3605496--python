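"""Mean-field solver: roots, thresholds, wave equilibrium, capacity."""

import numpy as np
import pytest

from synfire.engine import PropagationTable
from synfire.meanfield import (
    DegenerateSurvivalError,
    NoSolutionError,
    PropagationRow,
    _crossing_half,
    capacity_curve,
    equilibrium_state,
    equilibrium_waves,
    lambda_E_max,
    n_E_min,
    solve_selfconsistent,
)
from synfire.neurons import RateTable


def synthetic_tables(
    n_E_grid=(60, 80, 112),
    lam_grid=None,
    lam_half_of_nE=lambda ne: 0.25 * ne - 5.0,
    beta_Hz_per_kHz=0.02,
):
    """Smooth synthetic stand-ins for the simulation-derived tables.

    P_S rows are sigmoids dropping through 0.5 at a pool-size-dependent
    threshold rate; p_f and T vary weakly with background as the measured
    curves do; f_S is linear. Synthetic: used to exercise the numerics with
    known geometry, not to represent measured dynamics.
    """
    lam_grid = np.asarray(lam_grid if lam_grid is not None else np.linspace(0.5, 60, 120))
    n_E_grid = np.asarray(n_E_grid)
    P_S = np.empty((n_E_grid.size, lam_grid.size))
    p_f = np.empty_like(P_S)
    T = np.empty_like(P_S)
    for i, ne in enumerate(n_E_grid):
        lam_half = lam_half_of_nE(ne)
        # cliff width ~0.3 kHz, matching the steepness of measured curves
        z = np.clip((lam_grid - lam_half) / 0.3, -500.0, 500.0)
        P_S[i] = 1.0 / (1.0 + np.exp(z))
        p_f[i] = 0.95 - 0.002 * lam_grid
        T[i] = 2.7 + 0.005 * lam_grid
    prop = PropagationTable(n_E_grid, lam_grid, P_S, p_f, T, trials=100)
    rate = RateTable(lam_grid, beta_Hz_per_kHz * lam_grid, 0.25)
    return rate, prop


class TestCrossing:
    def test_interpolated_half_crossing(self):
        c = _crossing_half(
            np.array([10.0, 20, 30, 40, 50]), np.array([1.0, 1, 0.8, 0.2, 0])
        )
        assert c.value == pytest.approx(35.0)
        assert not c.out_of_range

    def test_no_crossing_flags_boundary(self):
        lam = np.array([10.0, 20.0])
        assert _crossing_half(lam, np.array([0.2, 0.1])) == (10.0, True)
        assert _crossing_half(lam, np.array([0.9, 0.8])) == (20.0, True)

    def test_threshold_rate_increases_with_pool_size(self):
        _, prop = synthetic_tables()
        vals = [lambda_E_max(ne, prop).value for ne in (60, 80, 112)]
        assert vals[0] < vals[1] < vals[2]

    def test_minimum_pool_size_inverts_threshold(self):
        _, prop = synthetic_tables()
        lam = lambda_E_max(80, prop).value
        c = n_E_min(lam, prop)
        assert not c.out_of_range
        assert c.value == pytest.approx(80.0, abs=1.0)


class TestSolveSelfConsistent:
    def test_silent_fixed_point(self):
        rate, prop = synthetic_tables(lam_grid=np.linspace(0.0, 60.0, 121))
        rate0 = RateTable(rate.lambda_E_grid, np.zeros_like(rate.rate_Hz), 0.25)
        sol = solve_selfconsistent(8000.0, 80, 0.0, (rate0, prop))
        assert sol.lambda_E == pytest.approx(0.0, abs=1e-3)
        assert sol.nu_S == 0.0 and sol.nu_W == 0.0

    def test_linear_closed_form(self):
        # p_f = 1, T = 3 ms, f_S = beta*lambda with C_E*beta < 1
        beta = 1e-5
        C_E, n_E, h_over_NE = 8000.0, 200, 26 / 80000
        grid = np.linspace(0.0, 300.0, 301)
        rate = RateTable(grid, 1000.0 * beta * grid, 0.25)
        prop = PropagationTable(
            np.array([200]), grid, np.ones((1, grid.size)),
            np.ones((1, grid.size)), np.full((1, grid.size), 3.0), 100,
        )
        sol = solve_selfconsistent(C_E, n_E, h_over_NE, (rate, prop))
        expected = C_E * h_over_NE * n_E / (3.0 * (1 - C_E * beta))
        assert sol.lambda_E == pytest.approx(expected, abs=1e-3)
        assert abs(sol.residual) < 1e-6 * max(1.0, sol.lambda_E)
        assert sol.nu == pytest.approx(sol.nu_W + sol.nu_S, rel=1e-12)

    def test_root_matches_independent_grid_scan(self):
        """Oracle: exhaustive fine-grid scan of the residual, independent of
        the bisection path."""
        rate, prop = synthetic_tables()
        C_E, n_E, h_over_NE = 4000.0, 80, 8 / 40000.0
        sol = solve_selfconsistent(C_E, n_E, h_over_NE, (rate, prop))

        row = PropagationRow(prop, n_E)
        lam_scan = np.linspace(0.5, 60.0, 300001)
        res = lam_scan - C_E * (
            h_over_NE * n_E * row.p_f(lam_scan) / row.T(lam_scan)
            + rate(lam_scan) / 1000.0
        )
        sign = np.sign(res)
        first = np.nonzero(np.diff(sign) != 0)[0][0]
        lam_oracle = lam_scan[first]
        assert sol.lambda_E == pytest.approx(lam_oracle, abs=2e-3)

    def test_no_sign_change_reports_residuals(self):
        rate, prop = synthetic_tables()
        with pytest.raises(NoSolutionError) as exc:
            solve_selfconsistent(1e7, 80, 10 / 1e4, (rate, prop))
        assert exc.value.residual_lo is not None


class TestEquilibriumWaves:
    def test_direct_evaluation(self):
        _, prop = synthetic_tables()
        row = PropagationRow(prop, 80)
        lam = lambda_E_max(80, prop).value  # P_S = 0.5 here
        w = equilibrium_waves(lam, row, T_stim=40.0, L=98)
        T = float(row.T(lam))
        assert w.T_S == pytest.approx(T * 98 / np.log(2.0), rel=1e-6)
        assert w.h_eq == pytest.approx(w.T_S / 40.0, rel=1e-12)

    def test_exponential_lifetime_example(self):
        lam_grid = np.array([10.0, 20.0])
        prop = PropagationTable(
            np.array([80]), lam_grid, np.full((1, 2), np.exp(-1.0)),
            np.full((1, 2), 0.9), np.full((1, 2), 3.0), 10,
        )
        w = equilibrium_waves(15.0, PropagationRow(prop, 80), T_stim=40.0, L=98)
        assert w.T_S == pytest.approx(294.0)
        assert w.h_eq == pytest.approx(7.35)

    def test_h_eq_monotone_as_survival_approaches_one(self):
        _, prop = synthetic_tables()
        row = PropagationRow(prop, 80)
        lam_half = lambda_E_max(80, prop).value
        lams = np.linspace(lam_half, lam_half - 3.0, 7)  # P_S rises toward 1
        h = [equilibrium_waves(x, row).h_eq for x in lams]
        assert np.all(np.diff(h) > 0)

    def test_degenerate_survival_raises(self):
        lam_grid = np.array([10.0, 20.0])
        prop = PropagationTable(
            np.array([80]), lam_grid, np.ones((1, 2)),
            np.full((1, 2), 0.9), np.full((1, 2), 3.0), 10,
        )
        with pytest.raises(DegenerateSurvivalError):
            equilibrium_waves(15.0, PropagationRow(prop, 80))


class TestEquilibriumState:
    def test_approximation_close_to_exact_root(self):
        """The lambda_E,max shortcut sits within one grid interval of the
        exact wave-balance root (the survival sigmoid is steep)."""
        rate, prop = synthetic_tables()
        pred = equilibrium_state(4000.0, 80, (rate, prop))
        dlam = np.diff(prop.lambda_E_grid).max()
        assert abs(pred.exact.lambda_E - pred.approx.lambda_E) < dlam
        assert pred.h_eq > 0
        assert pred.exact.nu >= pred.exact.nu_S


class TestCapacityCurve:
    def test_alpha_scales_inversely_with_squared_pool_size(self):
        rate, prop = synthetic_tables()
        curve = capacity_curve("nu_eq", 5.0, [3000.0, 4000.0], (rate, prop))
        np.testing.assert_allclose(
            curve.alpha_max, curve.C_E / curve.n_E_min**2, rtol=1e-12
        )

    def test_rises_then_flattens_with_connectivity(self):
        """At fixed firing rate, capacity grows quickly at low connectivity
        and its growth rate falls as n_E,min climbs with the background."""
        # lambda_E,max ~ k(n_E - n0): capacity rises ~linearly while the
        # conditioning background is small against n0, then levels off
        rate, prop = synthetic_tables(
            n_E_grid=(24, 40, 60, 80, 112),
            lam_half_of_nE=lambda ne: 0.25 * ne - 5.0,
        )
        C_E = np.linspace(300, 2600, 13)
        curve = capacity_curve("nu_eq", 5.0, C_E, (rate, prop))
        ok = ~np.isnan(curve.alpha_max)
        alpha = curve.alpha_max[ok]
        growth = np.diff(alpha) / np.diff(C_E[ok])
        assert growth[0] > 2.0 * abs(growth[-1])

    def test_wave_count_conditioning_produces_curve(self):
        rate, prop = synthetic_tables(n_E_grid=(60, 80, 112, 152))
        curve = capacity_curve(
            "h_over_NE", 5 / 80000.0, np.linspace(2000, 9000, 8), (rate, prop)
        )
        assert np.isfinite(curve.alpha_max[curve.valid]).all()
        assert curve.valid.any()

    def test_unknown_conditioning_rejected(self):
        rate, prop = synthetic_tables()
        with pytest.raises(ValueError):
            capacity_curve("nu", 5.0, [1000.0], (rate, prop))


class TestBackgroundCorrection:
    def test_neglected_fraction_has_documented_size(self):
        """The dropped background term n_E/(C_E(1+nu_S/nu_W)) is a few
        tenths of a percent to a few percent at reference-scale geometries."""
        rate, prop = synthetic_tables(
            n_E_grid=(60, 80, 112, 152, 200),
            lam_half_of_nE=lambda ne: 0.25 * ne - 5.0,
            lam_grid=np.linspace(0.5, 260, 520),
        )
        vals = []
        for C_E, ne in ((5000.0, 80), (8000.0, 112), (11000.0, 200)):
            sol = solve_selfconsistent(C_E, ne, 10.0 / (10 * C_E), (rate, prop))
            vals.append(sol.background_correction())
        assert all(0.001 < v < 0.05 for v in vals)
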