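"""Model/Results interface over the switch-model machinery.

`SwitchModel` wraps one gene's time course; `fit()` runs the
reversible-jump sampler and returns a `SwitchResults` holding the
posterior trace, the switch-time distribution with its Gaussian-mixture
summary, and point/interval estimates of the kinetic parameters.
`HierarchicalSwitchModel` does the same for one gene across several
experiments, pooling the degradation rate through the Gamma(mean, CV)
hyperdistribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ExpressionSeries, read_expression_long
from .kinetics import (KineticParameters, SwitchConfiguration,
                       fit_coefficients, solve_switch_model)
from .hierarchy import (HierarchicalTrace, HyperPriorSpec, run_hierarchical_chain,
                        stability_group)
from .sampler import MoveProbabilities, PosteriorTrace, PriorSpec, run_chain
from .summarize import SwitchDistribution, summarize_trace

__all__ = ["SwitchModel", "SwitchResults",
           "HierarchicalSwitchModel", "HierarchicalResults"]


class SwitchModel:
    """Temporal switch model of one gene's expression time course.

    Parameters
    ----------
    series : ExpressionSeries
        Observed times and replicate values on [0, L].
    priors : PriorSpec, optional
        Priors on switch count, degradation rate and precision.
    moves : MoveProbabilities, optional
        Dimension-move probabilities; derived from the priors by default.

    Examples
    --------
    >>> series, truth = simulate_gene(e1_like_design(), seed=1)
    >>> res = SwitchModel(series).fit(n_iter=20_000, burn_in=5_000, seed=1)
    >>> res.k_mode, res.half_life  # doctest: +SKIP
    """

    def __init__(self, series: ExpressionSeries, priors: PriorSpec | None = None,
                 moves: MoveProbabilities | None = None):
        self.series = series
        self.priors = priors or PriorSpec()
        self.moves = moves or MoveProbabilities.from_prior(self.priors)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene_id: str,
                       experiment_id: str | None = None,
                       priors: PriorSpec | None = None) -> "SwitchModel":
        """Build from a long-format expression table (see data module)."""
        series_list = read_expression_long(df)
        match = [s for s in series_list if s.gene_id == gene_id
                 and (experiment_id is None or s.experiment_id == experiment_id)]
        if not match:
            raise ValueError(f"gene {gene_id!r} not found")
        if len(match) > 1:
            raise ValueError(
                f"gene {gene_id!r} appears in several experiments; pass "
                "experiment_id or use HierarchicalSwitchModel")
        return cls(match[0], priors=priors)

    def fit(self, n_iter: int = 100_000, burn_in: int = 25_000,
            seed: int | None = None, **kwargs) -> "SwitchResults":
        """Run the reversible-jump chain and summarize the posterior."""
        trace = run_chain(self.series, priors=self.priors, moves=self.moves,
                          n_iter=n_iter, burn_in=burn_in, seed=seed, **kwargs)
        return SwitchResults(self, trace)


class SwitchResults:
    """Posterior of a fitted switch model.

    Attributes of interest: ``trace`` (the raw chain), ``k_mode``
    (posterior-mode number of switches), ``switch_distribution`` (density
    plus mixture summary), ``delta_mean`` / ``half_life`` and
    ``delta_interval``.
    """

    def __init__(self, model: SwitchModel, trace: PosteriorTrace):
        self.model = model
        self.trace = trace
        self._sd: SwitchDistribution | None = None

    @property
    def switch_distribution(self) -> SwitchDistribution:
        if self._sd is None:
            self._sd = summarize_trace(self.trace)
        return self._sd

    @property
    def k_mode(self) -> int:
        return self.trace.k_mode()

    @property
    def delta_mean(self) -> float:
        return float(self.trace.post_burn("delta").mean())

    @property
    def half_life(self) -> float:
        """Posterior-mean half-life ln 2 / delta (hours)."""
        return float(np.log(2.0) / self.delta_mean)

    @property
    def stability_group(self) -> str:
        return stability_group(self.half_life)

    def delta_interval(self, level: float = 0.90) -> tuple[float, float]:
        lo, hi = np.quantile(self.trace.post_burn("delta"),
                             [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def posterior_mean_curve(self, times=None) -> np.ndarray:
        """Fitted trajectory at representative posterior parameters.

        Uses the posterior-mean delta, the mixture means of the switch
        distribution as switch times (count = posterior-mode k where
        possible), and least-squares coefficients at those values.
        """
        series = self.model.series
        if times is None:
            times = series.times
        comps = sorted(self.switch_distribution.components,
                       key=lambda c: -c.weight)[: self.k_mode]
        s = np.sort([c.mean for c in comps])
        cfg = SwitchConfiguration(s, series.L)
        delta = self.delta_mean
        X0, beta = fit_coefficients(series, cfg, delta)
        return solve_switch_model(times, cfg, KineticParameters(delta, beta, X0))

    def summary(self) -> str:
        """Human-readable fit summary."""
        sd = self.switch_distribution
        lo, hi = self.delta_interval()
        lines = [
            "Temporal switch model — RJMCMC posterior summary",
            "=" * 52,
            f"gene: {self.model.series.gene_id}   experiment: "
            f"{self.model.series.experiment_id}",
            f"iterations: {self.trace.n_iter}  (burn-in {self.trace.burn_in})",
            f"posterior mode k: {self.k_mode}   "
            f"mixture components: {sd.n_switches}",
            f"degradation rate delta: {self.delta_mean:.4f} /h  "
            f"(90% CI {lo:.4f}-{hi:.4f})",
            f"half-life: {self.half_life:.2f} h  "
            f"(stability group {self.stability_group})",
            f"on/off switch samples: {sd.n_on}/{sd.n_off}",
            "",
            "switches (mean ± two-sigma band):",
        ]
        for i, c in enumerate(sd.components, 1):
            b = c.band
            lines.append(f"  s{i}: {c.mean:6.2f} h   band [{b[0]:6.2f}, "
                         f"{b[1]:6.2f}]   weight {c.weight:.3f}")
        if not sd.components:
            lines.append("  (none — effectively zero-switch gene)")
        acc = self.trace.acceptance_rates()
        lines.append("")
        lines.append("acceptance rates: " + ", ".join(
            f"{k}={v:.2f}" for k, v in acc.items()))
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        from .plotting import plot_fit
        return plot_fit(self, ax=ax)


class HierarchicalSwitchModel:
    """One gene across N experiments with a pooled degradation rate."""

    def __init__(self, series_list, hyperpriors: HyperPriorSpec | None = None,
                 priors: PriorSpec | None = None):
        if not series_list:
            raise ValueError("need at least one experiment")
        self.series_list = list(series_list)
        self.hyperpriors = hyperpriors or HyperPriorSpec()
        self.priors = priors or PriorSpec()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene_id: str,
                       **kwargs) -> "HierarchicalSwitchModel":
        series = [s for s in read_expression_long(df) if s.gene_id == gene_id]
        if not series:
            raise ValueError(f"gene {gene_id!r} not found")
        return cls(series, **kwargs)

    def fit(self, n_iter: int = 20_000, burn_in: int = 5_000,
            seed: int | None = None) -> "HierarchicalResults":
        trace = run_hierarchical_chain(self.series_list, self.hyperpriors,
                                       self.priors, n_iter=n_iter,
                                       burn_in=burn_in, seed=seed)
        return HierarchicalResults(self, trace)


class HierarchicalResults:
    """Posterior of the hierarchical degradation-rate model."""

    def __init__(self, model: HierarchicalSwitchModel,
                 trace: HierarchicalTrace):
        self.model = model
        self.trace = trace

    @property
    def mu_mean(self) -> float:
        return float(self.trace.post_burn_mu().mean())

    @property
    def cv_mean(self) -> float:
        return float(self.trace.post_burn_cv().mean())

    @property
    def pooled_half_life(self) -> float:
        return float(np.log(2.0) / self.mu_mean)

    def delta_posteriors(self) -> pd.DataFrame:
        """Per-experiment delta posterior quantiles plus the pooled
        hypermean row (box-plot style: 5/25/50/75/95 percentiles)."""
        qs = [0.05, 0.25, 0.5, 0.75, 0.95]
        rows = []
        for series, tr in zip(self.model.series_list,
                              self.trace.experiment_traces):
            d = tr.post_burn("delta")
            rows.append([series.experiment_id, *np.quantile(d, qs)])
        rows.append(["pooled (mu)", *np.quantile(self.trace.post_burn_mu(), qs)])
        return pd.DataFrame(rows, columns=["experiment", "q05", "q25", "q50",
                                           "q75", "q95"])

    def stability_table(self) -> pd.DataFrame:
        """Stability-group assignment per experiment and pooled."""
        rows = []
        for series, tr in zip(self.model.series_list,
                              self.trace.experiment_traces):
            hl = float(np.log(2.0) / tr.post_burn("delta").mean())
            rows.append([series.experiment_id, hl, stability_group(hl)])
        rows.append(["pooled (mu)", self.pooled_half_life,
                     stability_group(self.pooled_half_life)])
        return pd.DataFrame(rows, columns=["experiment", "half_life_h",
                                           "stability_group"])

    def summary(self) -> str:
        lines = [
            "Hierarchical degradation-rate pooling — posterior summary",
            "=" * 58,
            f"experiments: {len(self.model.series_list)}",
            f"hypermean mu: {self.mu_mean:.4f} /h   hyper-CV: "
            f"{self.cv_mean:.3f}",
            f"pooled half-life: {self.pooled_half_life:.2f} h "
            f"({stability_group(self.pooled_half_life)})",
            f"hyper acceptance rate: {self.trace.hyper_accept_rate:.2f}",
            "",
            self.stability_table().to_string(index=False),
        ]
        return "\n".join(lines)
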