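import numpy as np
import pytest

import txswitch as tx


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def one_switch_series():
    """Low-noise single-switch gene on the two-cycle protocol."""
    design = tx.e1_like_design(s=(20.0,), beta=(2.0, 0.2), delta=0.5,
                               noise="low")
    series, truth = tx.simulate_gene(design, seed=11)
    return series, truth


@pytest.fixture
def two_switch_series():
    series, truth = tx.simulate_gene(tx.e1_like_design(noise="medium"), seed=7)
    return series, truth


def random_instance(rng, k=None, L=48.0):
    """Random valid (config, params) pair for kinetics identities."""
    if k is None:
        k = int(rng.integers(0, 4))
    s = np.sort(rng.uniform(0.05 * L, 0.95 * L, size=k))
    while k >= 2 and np.min(np.diff(s)) < 0.02 * L:
        s = np.sort(rng.uniform(0.05 * L, 0.95 * L, size=k))
    config = tx.SwitchConfiguration(s, L)
    params = tx.KineticParameters(
        delta=float(rng.uniform(0.05, 2.0)),
        beta=rng.uniform(0.0, 5.0, size=k + 1),
        X0=float(rng.uniform(0.0, 5.0)),
    )
    return config, params


def _rk4_step_factor(delta, h):
    """Per-step multiplier of classical RK4 applied to x' = beta - delta x.

    For this linear autonomous ODE one RK4 step is exactly
    x+ = a x + (beta/delta)(1 - a) with a = 1 - delta w,
    w = (h/6)(6 - 6u + 4u^2 - 2u^3), u = delta h / 2 — the degree-4
    Taylor truncation of e^{-delta h}.
    """
    u = delta * h / 2.0
    w = (h / 6.0) * (6.0 - 6.0 * u + 4.0 * u * u - 2.0 * u ** 3)
    return 1.0 - delta * w


def rk4_trajectory(t_eval, config, params, step=1e-3):
    """Fixed-step RK4 integration of the piecewise-linear ODE
    dX/dt = beta(t) - delta X; oracle for the closed-form solution.

    Steps are aligned to regime boundaries and evaluation times; within a
    regime the (linear, constant-coefficient) RK4 recurrence is applied
    through its closed composition x_N = a^N x_0 + (beta/delta)(1 - a^N),
    reproducing the literal step-by-step sweep exactly without the loop.
    """
    t_eval = np.asarray(t_eval, float)
    delta = params.delta
    knots = np.unique(np.concatenate([config.boundaries, t_eval]))
    beta_of_seg = params.beta[
        np.clip(np.searchsorted(config.boundaries, knots[:-1], side="right")
                - 1, 0, params.beta.size - 1)]
    x = params.X0
    values = {0.0: x}
    for left, right, beta in zip(knots[:-1], knots[1:], beta_of_seg):
        width = right - left
        n_full = int(np.floor(width / step + 1e-9))
        rem = width - n_full * step
        a = _rk4_step_factor(delta, step) ** n_full
        if rem > 1e-12:
            a *= _rk4_step_factor(delta, rem)
        x = a * x + (beta / delta) * (1.0 - a)
        values[right] = x
    return np.array([values[t] for t in t_eval])
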