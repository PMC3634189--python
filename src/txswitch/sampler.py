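"""Reversible-jump MCMC over switch number, positions and kinetics.

One sweep of the chain performs, in order:

1. a dimension move — position change of a random switch, birth of a new
   switch, or death of an existing one, chosen with k-dependent
   probabilities (eta_k, b_k, d_k);
2. a random-walk Metropolis update of the degradation rate on the log
   scale;
3. a Gibbs draw of the residual precision tau from its conjugate Gamma
   conditional.

Transcription-rate coefficients (X0, beta) are never sampled: at every
likelihood evaluation they are computed by ordinary least squares at the
current (delta, s) — and, by default, integrated out analytically under a
flat prior, which uses only least-squares quantities but keeps the number
of switches identifiable (see PriorSpec.coefficient_likelihood).  No
Jacobian enters the Green acceptance rule

    alpha = min(1, likelihood ratio * prior ratio * proposal ratio).

The prior on the number of switches k is Poisson(lambda_k) truncated at
k_max; switch positions are a priori ordered-uniform on [0, L]; the birth
prior ratio is therefore p(k+1) (k+1) / (p(k) L), and a death's three
ratios are the exact inverses of the matching birth's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import ExpressionSeries
from .kinetics import gaussian_loglik, _profile_fit

__all__ = [
    "PriorSpec",
    "MoveProbabilities",
    "PosteriorTrace",
    "acceptance_probability",
    "birth_log_ratios",
    "death_log_ratios",
    "sample_precision",
    "run_chain",
]

MOVE_POSITION, MOVE_BIRTH, MOVE_DEATH = "position", "birth", "death"


@dataclass(frozen=True)
class PriorSpec:
    """Priors and fixed sampler constants.

    lambda_k, k_max
        Mean and truncation bound of the Poisson prior on the number of
        switches; lambda_k controls expected model complexity.
    a_tau, b_tau
        Shape/rate of the vague Gamma prior on the residual precision.
    log_delta_mean, log_delta_sd
        Weakly-informative Normal prior on log(delta).  The default centre
        log(0.2)/h corresponds to a half-life of ~3.5 h; sd 1.5 spans
        half-lives from minutes to days while keeping posterior mass out
        of the degenerate large-delta region, where coarse sampling makes
        the likelihood flat (regimes re-equilibrate between samples).
    s_min
        Minimum separation between switch times and from the interval
        boundaries.  ``None`` means "median spacing of the observation
        times", reflecting that switches without an observation between
        them are unidentifiable.
    delta_step
        Random-walk sd on log(delta).
    coefficient_likelihood
        ``"marginal"`` (default): dimension and delta moves compare models
        by the likelihood with the regression coefficients integrated out
        under a Zellner g-prior, beta ~ N(0, (g/tau)(X'X)^{-1}):

            -n/2 log(2pi/tau) - tau/2 (SSE + |Xb|^2/(1+g)) - p/2 log(1+g),

        computable from least-squares quantities alone and carrying the
        Occam penalty (p/2 log(1+g)) that keeps the number of switches
        identifiable.  ``"profiled"``: plain likelihood at the
        least-squares coefficients (no dimension penalty; prone to
        overfitting k; provided for comparison).
    g
        Scale of the g-prior; ``None`` (default) uses the benchmark
        choice g = max(n, p_max^2) with p_max = k_max + 2.
    """

    lambda_k: float = 2.0
    k_max: int = 10
    a_tau: float = 0.01
    b_tau: float = 0.01
    log_delta_mean: float = math.log(0.2)
    log_delta_sd: float = 1.5
    s_min: float | None = None
    delta_step: float = 0.15
    coefficient_likelihood: str = "marginal"
    g: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_k <= 0 or self.k_max < 1:
            raise ValueError("lambda_k > 0 and k_max >= 1 required")
        if self.a_tau <= 0 or self.b_tau <= 0 or self.log_delta_sd <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.coefficient_likelihood not in ("marginal", "profiled"):
            raise ValueError("coefficient_likelihood must be 'marginal' or 'profiled'")

    def resolve_s_min(self, times: np.ndarray) -> float:
        if self.s_min is not None:
            return float(self.s_min)
        return float(np.median(np.diff(np.sort(np.unique(times)))))

    def log_pmf_k(self, k: int) -> float:
        """Unnormalised truncated-Poisson log pmf (normaliser cancels in
        all ratios)."""
        if k < 0 or k > self.k_max:
            return -np.inf
        return k * math.log(self.lambda_k) - float(gammaln(k + 1))


@dataclass(frozen=True)
class MoveProbabilities:
    """Per-k probabilities of the three dimension moves.

    b_k = c min(1, p(k+1)/p(k)) and d_{k+1} = c min(1, p(k)/p(k+1)) with p
    the truncated-Poisson prior, so that b_k p(k) = d_{k+1} p(k+1) — the
    standard Green construction.  b_{k_max} = 0, d_0 = 0, and the position
    move takes the remainder eta_k = 1 - b_k - d_k.
    """

    birth: np.ndarray
    death: np.ndarray
    c: float = 0.4

    @classmethod
    def from_prior(cls, priors: PriorSpec, c: float = 0.4) -> "MoveProbabilities":
        if not 0 < c <= 0.5:
            raise ValueError("c must be in (0, 0.5] so that eta_k >= 0")
        kk = np.arange(priors.k_max + 1)
        lam = priors.lambda_k
        b = c * np.minimum(1.0, lam / (kk + 1.0))
        d = c * np.minimum(1.0, kk / lam)
        b[priors.k_max] = 0.0
        d[0] = 0.0
        return cls(birth=b, death=d, c=c)

    @property
    def position(self) -> np.ndarray:
        return 1.0 - self.birth - self.death


@dataclass
class PosteriorTrace:
    """Per-iteration record of the chain (burn-in included).

    Arrays ``k``, ``delta``, ``tau``, ``loglik`` have one entry per
    iteration; ``switch_times`` and ``betas`` are ragged lists aligned to
    them.  ``accepted``/``proposed`` count moves per type.
    """

    k: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    loglik: np.ndarray
    switch_times: list
    betas: list
    x0: np.ndarray
    burn_in: int
    seed: int | None
    L: float
    proposed: dict = field(default_factory=dict)
    accepted: dict = field(default_factory=dict)

    @property
    def n_iter(self) -> int:
        return self.k.size

    def post_burn(self, name: str) -> np.ndarray:
        return getattr(self, name)[self.burn_in:]

    def pooled_switch_times(self, thin: int = 1) -> np.ndarray:
        """All switch times from post-burn-in iterations, pooled."""
        sel = self.switch_times[self.burn_in::thin]
        if not any(s.size for s in sel):
            return np.empty(0)
        return np.concatenate([s for s in sel if s.size])

    def switch_events(self, thin: int = 1):
        """Yield (time, beta_before, beta_after) per post-burn-in switch."""
        for s, b in zip(self.switch_times[self.burn_in::thin],
                        self.betas[self.burn_in::thin]):
            for j in range(s.size):
                yield s[j], b[j], b[j + 1]

    def thin(self, factor: int) -> "PosteriorTrace":
        return PosteriorTrace(
            k=self.k[::factor], delta=self.delta[::factor],
            tau=self.tau[::factor], loglik=self.loglik[::factor],
            switch_times=self.switch_times[::factor],
            betas=self.betas[::factor], x0=self.x0[::factor],
            burn_in=-(-self.burn_in // factor), seed=self.seed, L=self.L,
            proposed=dict(self.proposed), accepted=dict(self.accepted))

    def k_mode(self) -> int:
        vals, counts = np.unique(self.post_burn("k"), return_counts=True)
        return int(vals[np.argmax(counts)])

    def acceptance_rates(self) -> dict:
        return {m: self.accepted.get(m, 0) / p
                for m, p in self.proposed.items() if p}

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "iteration": np.arange(self.n_iter), "k": self.k,
            "delta": self.delta, "tau": self.tau, "loglik": self.loglik})


def acceptance_probability(log_lik_ratio: float, log_prior_ratio: float,
                           log_proposal_ratio: float) -> float:
    """Green acceptance probability from log ratios.

    NaN in any ratio marks an invalid candidate and yields alpha = 0.
    """
    total = log_lik_ratio + log_prior_ratio + log_proposal_ratio
    if math.isnan(total):
        return 0.0
    return min(1.0, math.exp(min(total, 0.0)))


def _admissible_intervals(s: np.ndarray, L: float, s_min: float):
    """Intervals of [0, L] where a new switch may be born: s_min away from
    both boundaries and from every existing switch."""
    bounds = np.concatenate(([0.0], s, [L]))
    lows = bounds[:-1] + s_min
    highs = bounds[1:] - s_min
    keep = highs > lows
    return lows[keep], highs[keep]


def _admissible_length(s: np.ndarray, L: float, s_min: float) -> float:
    lows, highs = _admissible_intervals(s, L, s_min)
    return float(np.sum(highs - lows))


def birth_log_ratios(k: int, s: np.ndarray, L: float, s_min: float,
                     priors: PriorSpec, moves: MoveProbabilities
                     ) -> tuple[float, float]:
    """(log prior ratio, log proposal ratio) for a birth from (k, s).

    Prior ratio p(k+1)(k+1)/(p(k) L) combines the truncated-Poisson pmf
    with the ordered-uniform position density; the proposal ratio is
    d_{k+1}/((k+1) b_k q) with q = 1/|A| the uniform density on the
    admissible set and 1/(k+1) the reverse death's switch choice.
    """
    m = _admissible_length(s, L, s_min)
    if m <= 0 or k >= priors.k_max:
        return -np.inf, -np.inf
    log_prior = (priors.log_pmf_k(k + 1) - priors.log_pmf_k(k)
                 + math.log(k + 1.0) - math.log(L))
    log_prop = (math.log(moves.death[k + 1]) - math.log(k + 1.0)
                - math.log(moves.birth[k]) + math.log(m))
    return log_prior, log_prop


def death_log_ratios(k: int, s_reduced: np.ndarray, L: float, s_min: float,
                     priors: PriorSpec, moves: MoveProbabilities
                     ) -> tuple[float, float]:
    """(log prior ratio, log proposal ratio) for deleting one of k
    switches, leaving ``s_reduced``: the exact negations of the matching
    birth's ratios."""
    bp, bq = birth_log_ratios(k - 1, s_reduced, L, s_min, priors, moves)
    return -bp, -bq


def sample_precision(n_obs: int, sse: float, priors: PriorSpec,
                     rng: np.random.Generator, size=None):
    """Conjugate Gibbs draw tau ~ Gamma(a + n/2, b + SSE/2) (shape/rate)."""
    shape = priors.a_tau + 0.5 * n_obs
    rate = priors.b_tau + 0.5 * sse
    return rng.gamma(shape, 1.0 / rate, size=size)


class _Chain:
    """Mutable chain state plus update steps for a single series.

    ``delta_log_prior`` is the log prior density of delta expressed over
    log-delta space (i.e. including any Jacobian); the hierarchical model
    swaps it for the Gamma hyperdensity.
    """

    def __init__(self, series: ExpressionSeries, priors: PriorSpec,
                 moves: MoveProbabilities, rng: np.random.Generator,
                 likelihood_off: bool = False, delta_log_prior=None,
                 init_delta: float | None = None):
        self.series = series
        self.priors = priors
        self.moves = moves
        self.rng = rng
        self.likelihood_off = likelihood_off
        self.t = series.stacked_times
        self.y = series.stacked_values
        self.n = series.n_obs
        self.L = series.L
        self.s_min = priors.resolve_s_min(series.times)
        if delta_log_prior is None:
            delta_log_prior = self._vague_normal_log_prior
        self.delta_log_prior = delta_log_prior

        self.proposed = {m: 0 for m in (MOVE_POSITION, MOVE_BIRTH, MOVE_DEATH)}
        self.accepted = dict(self.proposed)
        self.proposed["delta"] = self.accepted["delta"] = 0

        self.marginal = priors.coefficient_likelihood == "marginal"
        if priors.g is not None:
            self.g = float(priors.g)
        else:
            self.g = float(max(self.n, (priors.k_max + 2) ** 2))
        self.yy = float(self.y @ self.y)

        # initial state: k = 0, delta at the prior centre
        self.s = np.empty(0)
        self.delta = float(init_delta if init_delta is not None
                           else math.exp(priors.log_delta_mean))
        self.coef, self.sse, ok, self.logdet = self._fit(self.s, self.delta)
        if not ok:
            raise ValueError("initial k=0 design is rank deficient")
        self.tau = float(self.n / self.sse) if self.sse > 0 else 1.0
        self.loglik = self._loglik(self.sse, self.s.size, self.logdet)

    # -- pieces -----------------------------------------------------------
    def _vague_normal_log_prior(self, delta: float) -> float:
        z = (math.log(delta) - self.priors.log_delta_mean) / self.priors.log_delta_sd
        return -0.5 * z * z

    def _fit(self, s: np.ndarray, delta: float):
        if self.likelihood_off:
            return np.zeros(s.size + 2), 0.0, True, 0.0
        bounds = np.concatenate(([0.0], s, [self.L]))
        return _profile_fit(self.t, self.y, bounds, delta, self.L)

    def _loglik(self, sse: float, k: int, logdet: float) -> float:
        """Working log-likelihood at the current tau.

        "marginal": regression coefficients integrated out under the
        g-prior (see PriorSpec); the p/2 log(1+g) dimension penalty makes
        k identifiable.  "profiled": plain Gaussian log-likelihood at the
        least-squares coefficients.
        """
        if self.likelihood_off:
            return 0.0
        if self.marginal:
            p = k + 2
            fit_sq = max(self.yy - sse, 0.0)
            return (gaussian_loglik(self.n, sse + fit_sq / (1.0 + self.g),
                                    self.tau)
                    - 0.5 * p * math.log(1.0 + self.g))
        return gaussian_loglik(self.n, sse, self.tau)

    @property
    def k(self) -> int:
        return self.s.size

    # -- dimension moves --------------------------------------------------
    def dimension_move(self) -> None:
        k = self.k
        u = self.rng.random()
        if u < self.moves.birth[k]:
            self._birth()
        elif u < self.moves.birth[k] + self.moves.death[k]:
            self._death()
        else:
            self._position()

    def _try_accept(self, move: str, s_new: np.ndarray, log_prior: float,
                    log_prop: float) -> None:
        self.proposed[move] += 1
        coef, sse, ok, logdet = self._fit(s_new, self.delta)
        if not ok:
            return
        ll = self._loglik(sse, s_new.size, logdet)
        alpha = acceptance_probability(ll - self.loglik, log_prior, log_prop)
        if self.rng.random() < alpha:
            self.accepted[move] += 1
            self.s, self.coef, self.sse = s_new, coef, sse
            self.loglik, self.logdet = ll, logdet

    def _position(self) -> None:
        if self.k == 0:
            return  # position move on empty configuration is a no-op
        j = int(self.rng.integers(self.k))
        bounds = np.concatenate(([0.0], self.s, [self.L]))
        low = bounds[j] + self.s_min
        high = bounds[j + 2] - self.s_min
        self.proposed[MOVE_POSITION] += 1
        if high <= low:
            return
        s_new = self.s.copy()
        s_new[j] = self.rng.uniform(low, high)
        # window is identical for the reverse move: proposal ratio 1;
        # ordered-uniform prior unchanged: prior ratio 1
        coef, sse, ok, logdet = self._fit(s_new, self.delta)
        if not ok:
            return
        ll = self._loglik(sse, s_new.size, logdet)
        if self.rng.random() < acceptance_probability(ll - self.loglik, 0.0, 0.0):
            self.accepted[MOVE_POSITION] += 1
            self.s, self.coef, self.sse = s_new, coef, sse
            self.loglik, self.logdet = ll, logdet

    def _birth(self) -> None:
        k = self.k
        lows, highs = _admissible_intervals(self.s, self.L, self.s_min)
        m = float(np.sum(highs - lows))
        self.proposed[MOVE_BIRTH] += 1
        if m <= 0:
            return
        u = self.rng.uniform(0.0, m)
        cum = np.cumsum(highs - lows)
        i = int(np.searchsorted(cum, u, side="right"))
        s_star = lows[i] + u - (cum[i - 1] if i else 0.0)
        s_new = np.sort(np.append(self.s, s_star))
        log_prior, log_prop = birth_log_ratios(k, self.s, self.L, self.s_min,
                                               self.priors, self.moves)
        self._try_accept(MOVE_BIRTH, s_new, log_prior, log_prop)

    def _death(self) -> None:
        k = self.k
        if k == 0:
            return
        self.proposed[MOVE_DEATH] += 1
        j = int(self.rng.integers(k))
        s_new = np.delete(self.s, j)
        # exact inverses of the birth that would re-insert s_j
        log_prior, log_prop = death_log_ratios(k, s_new, self.L, self.s_min,
                                               self.priors, self.moves)
        if not math.isfinite(log_prior):
            return
        self._try_accept(MOVE_DEATH, s_new, log_prior, log_prop)

    # -- within-model updates --------------------------------------------
    def update_delta(self) -> None:
        """Random-walk Metropolis on log(delta); coefficients refit at the
        candidate."""
        self.proposed["delta"] += 1
        log_d = math.log(self.delta)
        log_d_new = log_d + self.priors.delta_step * self.rng.standard_normal()
        d_new = math.exp(log_d_new)
        if not np.isfinite(d_new) or d_new <= 0:
            return
        coef, sse, ok, logdet = self._fit(self.s, d_new)
        if not ok or not np.isfinite(sse):
            return
        ll = self._loglik(sse, self.s.size, logdet)
        log_ratio = (ll - self.loglik
                     + self.delta_log_prior(d_new) - self.delta_log_prior(self.delta))
        if math.isnan(log_ratio):
            return
        if self.rng.random() < min(1.0, math.exp(min(log_ratio, 0.0))):
            self.accepted["delta"] += 1
            self.delta, self.coef, self.sse = d_new, coef, sse
            self.loglik, self.logdet = ll, logdet

    def update_tau(self) -> None:
        """Conjugate Gibbs draw: tau ~ Gamma(a + n/2, b + SSE/2)."""
        self.tau = float(sample_precision(self.n, self.sse, self.priors,
                                          self.rng))
        self.loglik = self._loglik(self.sse, self.s.size, self.logdet)

    def sweep(self) -> None:
        self.dimension_move()
        self.update_delta()
        self.update_tau()


def run_chain(series: ExpressionSeries, priors: PriorSpec | None = None,
              moves: MoveProbabilities | None = None, n_iter: int = 100_000,
              burn_in: int = 25_000, seed: int | None = None,
              likelihood_off: bool = False,
              delta_log_prior=None, init_delta: float | None = None
              ) -> PosteriorTrace:
    """Run the reversible-jump chain for one gene.

    Parameters mirror :class:`PriorSpec`; ``likelihood_off`` replaces the
    likelihood with a constant, so the chain samples the prior — the
    standard correctness check for a reversible-jump sampler.

    Returns a :class:`PosteriorTrace` with one record per sweep,
    reproducible given ``seed``.
    """
    if burn_in < 0 or n_iter <= burn_in:
        raise ValueError("need n_iter > burn_in >= 0")
    priors = priors or PriorSpec()
    moves = moves or MoveProbabilities.from_prior(priors)
    rng = np.random.default_rng(seed)
    chain = _Chain(series, priors, moves, rng, likelihood_off=likelihood_off,
                   delta_log_prior=delta_log_prior, init_delta=init_delta)

    k_arr = np.empty(n_iter, dtype=np.int32)
    d_arr = np.empty(n_iter)
    t_arr = np.empty(n_iter)
    ll_arr = np.empty(n_iter)
    x0_arr = np.empty(n_iter)
    s_list: list = [None] * n_iter
    b_list: list = [None] * n_iter
    for it in range(n_iter):
        chain.sweep()
        k_arr[it] = chain.k
        d_arr[it] = chain.delta
        t_arr[it] = chain.tau
        ll_arr[it] = chain.loglik
        x0_arr[it] = chain.coef[0]
        s_list[it] = chain.s.copy()
        b_list[it] = chain.coef[1:].copy()
    return PosteriorTrace(k=k_arr, delta=d_arr, tau=t_arr, loglik=ll_arr,
                          switch_times=s_list, betas=b_list, x0=x0_arr,
                          burn_in=burn_in, seed=seed, L=series.L,
                          proposed=chain.proposed, accepted=chain.accepted)
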