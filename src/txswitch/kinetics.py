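"""Closed-form solution of the piecewise-linear switch ODE and its linear form.

The switch model for mRNA concentration X(t) on [0, L] is

    dX/dt = beta_j - delta * X     for  t in [s_{j-1}, s_j),

with regime boundaries 0 = s_0 < s_1 < ... < s_k < s_{k+1} = L: the
transcription rate beta jumps at the (unknown) switch times while the
first-order degradation rate delta is shared by all regimes.  Solving each
linear regime and chaining final states as initial conditions gives the
closed form

    X(t) = X0 e^{-delta t}
         + sum_i (beta_i/delta) (e^{-delta max(0, t - s_i)} - e^{-delta (t - s_{i-1})})

for t >= s_{i-1} (regimes the trajectory has not reached contribute zero).
Because X(t) is linear in (X0, beta_1..beta_{k+1}), those coefficients can
be profiled out by ordinary least squares at any (delta, s), which is what
the sampler does at every likelihood evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionSeries

__all__ = [
    "SwitchConfiguration",
    "KineticParameters",
    "ModelState",
    "solve_switch_model",
    "design_matrix",
    "fit_coefficients",
    "log_likelihood",
    "RankDeficientDesign",
]

# below delta*L ~ 1e-8 the expm1 quotient is replaced by its linear limit
_SMALL_DELTA_L = 1e-8


class RankDeficientDesign(ValueError):
    """Raised when the least-squares design cannot identify all coefficients
    (e.g. two consecutive switches with no observation between them)."""


@dataclass(frozen=True)
class SwitchConfiguration:
    """Ordered interior switch times on (0, L).

    Attributes
    ----------
    s : ndarray
        Switch times s_1 < ... < s_k; may be empty (k = 0).
    L : float
        Observation-interval length (hours).
    s_min : float
        Minimum separation between consecutive switches and from the
        boundaries 0 and L.
    """

    s: np.ndarray
    L: float
    s_min: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.s_min < 0:
            raise ValueError("s_min must be non-negative")
        if self.s.size:
            bounds = np.concatenate(([0.0], np.sort(self.s), [self.L]))
            if not np.array_equal(bounds[1:-1], self.s):
                raise ValueError("switch times must be sorted")
            if np.any(np.diff(bounds) < self.s_min - 1e-12):
                raise ValueError("switch times violate the s_min separation")
            if self.s[0] <= 0 or self.s[-1] >= self.L:
                raise ValueError("switch times must lie strictly inside (0, L)")

    @property
    def k(self) -> int:
        return int(self.s.size)

    @property
    def boundaries(self) -> np.ndarray:
        """Regime boundaries [0, s_1, ..., s_k, L] (length k + 2)."""
        return np.concatenate(([0.0], self.s, [self.L]))


@dataclass(frozen=True)
class KineticParameters:
    """Degradation rate, per-regime transcription rates, initial condition.

    ``beta`` has one entry per regime (k + 1 of them); entries are not
    constrained to be non-negative, matching the unconstrained least-squares
    estimator (expression units are only proportional to concentration, so
    the coefficient scale is arbitrary anyway).
    """

    delta: float
    beta: np.ndarray
    X0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    @property
    def half_life(self) -> float:
        return float(np.log(2.0) / self.delta)


@dataclass
class ModelState:
    """One sampler state: switch configuration, kinetic parameters, residual
    precision tau = 1/sigma^2, and the cached log-likelihood."""

    config: SwitchConfiguration
    params: KineticParameters
    tau: float
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.params.beta.size != self.config.k + 1:
            raise ValueError("need one beta per regime (k + 1)")


def _regime_basis(times: np.ndarray, boundaries: np.ndarray, delta: float,
                  L: float) -> np.ndarray:
    """Columns f_i(t) for each regime i; f_i(t) = 0 for t <= s_{i-1}.

    f_i(t) = e^{-delta (t - cap)} * (1 - e^{-delta (cap - low)}) / delta with
    cap = min(t, s_i), computed through expm1 so the small-delta limit
    f_i -> (cap - low) is reached smoothly.
    """
    t = np.asarray(times, dtype=float)
    n_reg = boundaries.size - 1
    out = np.zeros((t.size, n_reg))
    small = delta * L < _SMALL_DELTA_L
    for i in range(n_reg):
        low, high = boundaries[i], boundaries[i + 1]
        active = t > low
        if not np.any(active):
            continue
        ta = t[active]
        cap = np.minimum(ta, high)
        if small:
            out[active, i] = cap - low
        else:
            out[active, i] = (
                np.exp(-delta * (ta - cap)) * (-np.expm1(-delta * (cap - low))) / delta
            )
    return out


def design_matrix(times, config: SwitchConfiguration, delta: float) -> np.ndarray:
    """Design matrix of the linear-model form of the switch ODE.

    Row per time, column 0 = e^{-delta t} (coefficient X0), column i =
    regime basis f_i(t) (coefficient beta_i), so that
    ``design_matrix(t, c, d) @ [X0, beta]`` equals
    :func:`solve_switch_model` exactly.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    t = np.asarray(times, dtype=float)
    decay = np.exp(-delta * t)[:, None]
    return np.hstack([decay, _regime_basis(t, config.boundaries, delta, config.L)])


def solve_switch_model(times, config: SwitchConfiguration,
                       params: KineticParameters) -> np.ndarray:
    """Concentration X(t) of the switch model at the given times."""
    if params.beta.size != config.k + 1:
        raise ValueError("need one beta per regime (k + 1)")
    A = design_matrix(times, config, params.delta)
    x = A @ np.concatenate(([params.X0], params.beta))
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite model output; invalid parameters")
    return x


def fit_coefficients(series: ExpressionSeries, config: SwitchConfiguration,
                     delta: float) -> tuple[float, np.ndarray]:
    """Profile (X0, beta) by ordinary least squares at fixed (delta, s).

    Stacks all replicates, drops missing cells.  Raises
    :class:`RankDeficientDesign` when a regime contains no observation (the
    corresponding rate is unidentifiable).
    """
    coef, _, ok, _ = _profile_fit(series.stacked_times, series.stacked_values,
                                  config.boundaries, delta, config.L)
    if not ok:
        raise RankDeficientDesign(
            f"design is rank deficient for k={config.k} at delta={delta:g}; "
            "likely a regime without observations"
        )
    return float(coef[0]), coef[1:]


def _profile_fit(t: np.ndarray, y: np.ndarray, boundaries: np.ndarray,
                 delta: float, L: float
                 ) -> tuple[np.ndarray, float, bool, float]:
    """Least-squares coefficients, SSE and log|X'X| for stacked data.

    Returns (coef, sse, full_rank, logdet_xtx); never raises.  Used in the
    sampler hot path, where a rank-deficient candidate is simply rejected
    and log|X'X| feeds the coefficient-marginalized likelihood.
    """
    A = np.hstack([np.exp(-delta * t)[:, None],
                   _regime_basis(t, boundaries, delta, L)])
    q, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        return np.zeros(A.shape[1]), np.inf, False, -np.inf
    qty = q.T @ y
    coef = solve_triangular_upper(r, qty)
    sse = max(float(y @ y - qty @ qty), 0.0)
    logdet = 2.0 * float(np.log(diag).sum())
    return coef, sse, True, logdet


def solve_triangular_upper(r: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular
    return solve_triangular(r, b, lower=False, check_finite=False)


def log_likelihood(series: ExpressionSeries, state: ModelState) -> float:
    """Gaussian log-likelihood of the series under a model state.

    Residuals between the closed-form trajectory and every non-missing
    observation are i.i.d. Normal(0, 1/tau):

        loglik = -(n/2) log(2 pi / tau) - (tau/2) * SSE.
    """
    try:
        x = solve_switch_model(series.stacked_times, state.config, state.params)
    except FloatingPointError:
        return -np.inf
    resid = series.stacked_values - x
    sse = float(resid @ resid)
    n = series.n_obs
    return gaussian_loglik(n, sse, state.tau)


def gaussian_loglik(n: int, sse: float, tau: float) -> float:
    """Closed-form i.i.d. Gaussian log-likelihood from sufficient statistics."""
    return -0.5 * n * np.log(2.0 * np.pi / tau) - 0.5 * tau * sse
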