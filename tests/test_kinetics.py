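"""Closed-form switch ODE, design-matrix identity, least squares, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import txswitch as tx
from txswitch.kinetics import RankDeficientDesign, gaussian_loglik

from conftest import random_instance, rk4_trajectory


class TestSolveSwitchModel:
    def test_pure_exponential_decay(self):
        """With no transcription, X0 = 1 and delta = ln 2, the
        concentration halves every hour."""
        cfg = tx.SwitchConfiguration(np.empty(0), 10.0)
        par = tx.KineticParameters(np.log(2.0), np.array([0.0]), X0=1.0)
        x = tx.solve_switch_model(np.array([0.0, 1.0, 2.0, 3.0]), cfg, par)
        assert np.allclose(x, [1.0, 0.5, 0.25, 0.125], rtol=1e-12)

    def test_steady_state_is_fixed_point(self):
        cfg = tx.SwitchConfiguration(np.empty(0), 20.0)
        par = tx.KineticParameters(0.7, np.array([2.1]), X0=2.1 / 0.7)
        x = tx.solve_switch_model(np.linspace(0, 20, 11), cfg, par)
        assert np.allclose(x, 2.1 / 0.7, rtol=1e-12)

    def test_matches_rk4_oracle(self, rng):
        """Closed form vs independent RK4 integration on random valid
        instances."""
        worst = 0.0
        for _ in range(20):
            cfg, par = random_instance(rng)
            t = np.linspace(0.0, 48.0, 25)
            closed = tx.solve_switch_model(t, cfg, par)
            oracle = rk4_trajectory(t, cfg, par)
            worst = max(worst, np.max(np.abs(closed - oracle)
                                      / np.maximum(np.abs(oracle), 1e-9)))
        assert worst <= 1e-8

    def test_continuity_at_switch_points(self, rng):
        """Concentration is continuous across switches; only the slope
        jumps."""
        for _ in range(20):
            cfg, par = random_instance(rng, k=2)
            for sj in cfg.s:
                left, right = tx.solve_switch_model(
                    np.array([sj - 1e-9, sj + 1e-9]), cfg, par)
                assert abs(left - right) <= 1e-6
            exact = tx.solve_switch_model(cfg.s, cfg, par)
            before = tx.solve_switch_model(cfg.s - 1e-9, cfg, par)
            assert np.all(np.abs(exact - before) <= 1e-6)

    def test_small_delta_limit(self):
        """As delta -> 0 each regime contributes beta_i times its overlap
        with [0, t]; the guard branch agrees with the full formula."""
        s = np.array([8.0, 20.0])
        beta = np.array([2.0, 0.5, 1.0])
        t = np.array([4.0, 10.0, 30.0, 48.0])
        overlap = np.array([
            [min(ti, 8.0), max(0.0, min(ti, 20.0) - 8.0),
             max(0.0, ti - 20.0)] for ti in t])
        expected = overlap @ beta + 3.0  # X0 e^{-delta t} -> X0
        # the limit is approached at rate O(delta * L) ~ 5e-5 at delta=1e-6
        for delta in (1e-6, 1e-10):
            cfg = tx.SwitchConfiguration(s, 48.0)
            par = tx.KineticParameters(delta, beta, X0=3.0)
            x = tx.solve_switch_model(t, cfg, par)
            assert np.allclose(x, expected, rtol=1e-4)
        # guard branch (delta*L < 1e-8) vs full formula at delta = 1e-6
        cfg = tx.SwitchConfiguration(s, 48.0)
        full = tx.solve_switch_model(t, cfg,
                                     tx.KineticParameters(1e-6, beta, 3.0))
        guarded = tx.solve_switch_model(t, cfg,
                                        tx.KineticParameters(1e-11, beta, 3.0))
        assert np.allclose(full, guarded, rtol=1e-4)


class TestDesignMatrix:
    def test_k0_columns(self):
        """Single regime: [e^{-delta t}, (1/delta)(1 - e^{-delta t})]."""
        t = np.linspace(0, 10, 6)
        cfg = tx.SwitchConfiguration(np.empty(0), 10.0)
        A = tx.design_matrix(t, cfg, 0.3)
        assert A.shape == (6, 2)
        assert np.allclose(A[:, 0], np.exp(-0.3 * t))
        assert np.allclose(A[:, 1], (1 - np.exp(-0.3 * t)) / 0.3)

    def test_telescoping_sum(self, rng):
        """Sum of regime columns collapses to the constant-transcription
        solution (1/delta)(1 - e^{-delta t})."""
        for _ in range(10):
            cfg, par = random_instance(rng)
            t = np.linspace(0, 48, 30)
            A = tx.design_matrix(t, cfg, par.delta)
            total = A[:, 1:].sum(axis=1)
            expected = (1 - np.exp(-par.delta * t)) / par.delta
            assert np.allclose(total, expected, atol=1e-10)

    def test_linear_form_equals_closed_form(self, rng):
        """matrix @ [X0, beta] reproduces the closed-form solution."""
        for _ in range(50):
            cfg, par = random_instance(rng)
            t = np.sort(rng.uniform(0, 48, size=20))
            A = tx.design_matrix(t, cfg, par.delta)
            lin = A @ np.concatenate([[par.X0], par.beta])
            closed = tx.solve_switch_model(t, cfg, par)
            assert np.max(np.abs(lin - closed)) <= 1e-12

    def test_basis_zero_before_regime_start(self):
        cfg = tx.SwitchConfiguration(np.array([10.0, 30.0]), 48.0)
        A = tx.design_matrix(np.array([5.0, 10.0, 29.0]), cfg, 0.5)
        assert A[0, 2] == 0.0 and A[0, 3] == 0.0  # t=5 before both switches
        assert A[1, 2] == 0.0  # t = s_1 boundary: regime 2 still empty
        assert A[2, 3] == 0.0


class TestFitCoefficients:
    def test_exact_recovery_on_noiseless_data(self, rng):
        for _ in range(10):
            cfg, par = random_instance(rng, k=2)
            t = np.linspace(0, 48, 13)
            x = tx.solve_switch_model(t, cfg, par)
            series = tx.ExpressionSeries("g", "e", t, np.vstack([x, x]),
                                         L=48.0)
            X0, beta = tx.fit_coefficients(series, cfg, par.delta)
            assert abs(X0 - par.X0) <= 1e-6
            assert np.max(np.abs(beta - par.beta)) <= 1e-6

    def test_constant_data_steady_state(self):
        t = np.linspace(0, 10, 8)
        series = tx.ExpressionSeries("g", "e", t, np.full((1, 8), 3.5),
                                     L=10.0)
        cfg = tx.SwitchConfiguration(np.empty(0), 10.0)
        X0, beta = tx.fit_coefficients(series, cfg, 0.5)
        fitted = tx.solve_switch_model(
            t, cfg, tx.KineticParameters(0.5, beta, X0))
        assert np.allclose(fitted, 3.5, atol=1e-8)

    def test_unobserved_regime_raises(self):
        """A regime with no observation at or after its start has an
        all-zero design column; the fit reports it instead of silently
        regularizing."""
        t = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        series = tx.ExpressionSeries("g", "e", t, np.ones((1, 5)), L=48.0)
        cfg = tx.SwitchConfiguration(np.array([42.0, 46.0]), 48.0)
        with pytest.raises(RankDeficientDesign):
            tx.fit_coefficients(series, cfg, 0.5)

    def test_least_squares_optimality_on_noisy_data(self, rng):
        cfg, par = random_instance(rng, k=1)
        t = np.linspace(0, 48, 13)
        x = tx.solve_switch_model(t, cfg, par)
        y = x + 0.3 * rng.standard_normal((2, 13))
        series = tx.ExpressionSeries("g", "e", t, y, L=48.0)
        X0, beta = tx.fit_coefficients(series, cfg, par.delta)
        fit = tx.solve_switch_model(t, cfg,
                                    tx.KineticParameters(par.delta, beta, X0))
        sse_fit = np.sum((y - fit) ** 2)
        sse_truth = np.sum((y - x) ** 2)
        assert sse_fit <= sse_truth + 1e-10

    def test_missing_cells_are_dropped(self):
        t = np.linspace(0, 10, 6)
        vals = np.vstack([np.ones(6), np.ones(6)])
        vals[1, 2] = np.nan
        series = tx.ExpressionSeries("g", "e", t, vals, L=10.0)
        assert series.n_obs == 11
        cfg = tx.SwitchConfiguration(np.empty(0), 10.0)
        X0, beta = tx.fit_coefficients(series, cfg, 0.4)
        assert np.isfinite(X0) and np.all(np.isfinite(beta))


class TestLogLikelihood:
    def _state(self, cfg, par, tau):
        return tx.ModelState(cfg, par, tau)

    def test_zero_residuals_closed_form(self):
        """Perfect fit with n = 20, tau = 1 gives -10 log(2 pi)."""
        t = np.linspace(0, 10, 10)
        cfg = tx.SwitchConfiguration(np.empty(0), 10.0)
        par = tx.KineticParameters(0.5, np.array([1.0]), X0=2.0)
        x = tx.solve_switch_model(t, cfg, par)
        series = tx.ExpressionSeries("g", "e", t, np.vstack([x, x]), L=10.0)
        ll = tx.log_likelihood(series, self._state(cfg, par, 1.0))
        assert np.isclose(ll, -10.0 * np.log(2 * np.pi), rtol=1e-12)

    def test_tau_scaling_identity(self):
        n, sse = 24, 7.3
        tau = 0.8
        diff = gaussian_loglik(n, sse, 2 * tau) - gaussian_loglik(n, sse, tau)
        assert np.isclose(diff, (n / 2) * np.log(2) - (sse / 2) * tau)

    def test_matches_pointwise_normal_density_sum(self, rng):
        """Independent oracle: sum of per-observation Normal log densities."""
        cfg, par = random_instance(rng, k=1)
        t = np.linspace(0, 48, 13)
        x = tx.solve_switch_model(t, cfg, par)
        y = x + 0.4 * rng.standard_normal((2, 13))
        series = tx.ExpressionSeries("g", "e", t, y, L=48.0)
        tau = 1.7
        ll = tx.log_likelihood(series, self._state(cfg, par, tau))
        sigma = 1.0 / np.sqrt(tau)
        oracle = stats.norm.logpdf(y, loc=x[None, :], scale=sigma).sum()
        assert abs(ll - oracle) <= 1e-10


@settings(deadline=None, max_examples=30, derandomize=True)
@given(delta=st.floats(0.01, 3.0), x0=st.floats(0.0, 5.0),
       beta0=st.floats(0.0, 5.0), beta1=st.floats(0.0, 5.0),
       s1=st.floats(2.0, 46.0))
def test_trajectory_continuous_and_finite(delta, x0, beta0, beta1, s1):
    """Property: any valid 1-switch trajectory is finite everywhere and
    continuous at the switch."""
    cfg = tx.SwitchConfiguration(np.array([s1]), 48.0)
    par = tx.KineticParameters(delta, np.array([beta0, beta1]), x0)
    t = np.linspace(0, 48, 97)
    x = tx.solve_switch_model(t, cfg, par)
    assert np.all(np.isfinite(x))
    lo, hi = tx.solve_switch_model(np.array([s1 - 1e-8, s1 + 1e-8]), cfg, par)
    assert abs(hi - lo) <= 1e-5
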