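"""Switch-time distributions: kernel density, mixture summary, on/off split.

The pooled post-burn-in switch times from a chain are turned into a
density on [0, L] (the "switch-time distribution", SD).  Local maxima of
the density are taken as candidate switches and a Gaussian mixture is
fitted to the density curve itself; each component's mean and two-sigma
band summarize one reported switch.  Every sampled switch is an on-switch
(transcription rate increases across it) or an off-switch (rate
decreases), and separate densities over the two subsets support the
on/off clustering pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .sampler import PosteriorTrace

__all__ = [
    "MixtureComponent",
    "SwitchDistribution",
    "estimate_switch_density",
    "fit_mixture_summary",
    "classify_on_off",
    "summarize_trace",
]


@dataclass(frozen=True)
class MixtureComponent:
    mean: float
    sigma: float
    weight: float

    @property
    def band(self) -> tuple[float, float]:
        """Two-sigma band around the switch location."""
        return (self.mean - 2.0 * self.sigma, self.mean + 2.0 * self.sigma)


@dataclass
class SwitchDistribution:
    """Density of accepted switch times over [0, L] plus its summary.

    ``density`` integrates to 1 over the grid (trapezoid); ``on_density``
    and ``off_density`` are each normalized too, with ``on_weight`` /
    ``off_weight`` chosen so that the weighted sum reproduces ``density``
    pointwise.  ``components`` is the Gaussian-mixture summary, ordered by
    mean; empty when the gene never sampled a switch.
    """

    grid: np.ndarray
    density: np.ndarray
    on_density: np.ndarray
    off_density: np.ndarray
    on_weight: float
    off_weight: float
    components: list = field(default_factory=list)
    n_samples: int = 0
    n_on: int = 0
    n_off: int = 0
    L: float = 0.0

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    @property
    def n_switches(self) -> int:
        """Reported number of switches = mixture components."""
        return len(self.components)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_h": self.grid, "density": self.density,
                             "on_density": self.on_density,
                             "off_density": self.off_density})

    def summary_dict(self) -> dict:
        return {
            "n_samples": int(self.n_samples),
            "n_on": int(self.n_on), "n_off": int(self.n_off),
            "switches": [
                {"mean": c.mean, "sigma": c.sigma, "weight": c.weight,
                 "band": list(c.band)} for c in self.components],
        }


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    if n < 2:
        return 1e-2
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        return 1e-2
    return 0.9 * scale * n ** (-0.2)


def _kde_on_grid(samples: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Gaussian KDE with explicit bandwidth, renormalized to the grid.

    A shared explicit bandwidth (Silverman's rule on the pooled samples)
    is used for whole / on / off variants so the subset densities add
    exactly to the whole one.
    """
    if samples.size == 0:
        return np.zeros_like(grid)
    # evaluate in manageable blocks: samples may number 10^5+
    dens = np.zeros_like(grid)
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * h * samples.size)
    for start in range(0, samples.size, 4096):
        blk = samples[start:start + 4096]
        z = (grid[:, None] - blk[None, :]) / h
        dens += norm * np.exp(-0.5 * z * z).sum(axis=1)
    return dens


def _normalize(grid: np.ndarray, dens: np.ndarray) -> tuple[np.ndarray, float]:
    integral = float(np.trapezoid(dens, grid))
    if integral <= 0:
        return dens, 0.0
    return dens / integral, integral


def estimate_switch_density(trace: PosteriorTrace, grid_size: int = 512,
                            bandwidth: float | None = None,
                            thin: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """KDE of all post-burn-in switch times on a regular grid over [0, L].

    Returns (grid, density); density integrates to 1 by trapezoid.  A
    trace that never sampled a switch yields an all-zero density (the gene
    is effectively 0-switch).
    """
    grid = np.linspace(0.0, trace.L, grid_size)
    samples = trace.pooled_switch_times(thin=thin)
    if samples.size == 0:
        return grid, np.zeros_like(grid)
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(samples)
    dens, _ = _normalize(grid, _kde_on_grid(samples, grid, h))
    return grid, dens


def _local_maxima(grid: np.ndarray, dens: np.ndarray, floor_frac: float):
    peak = dens.max()
    if peak <= 0:
        return []
    idx = []
    for i in range(1, dens.size - 1):
        if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1]:
            if dens[i] >= floor_frac * peak:
                idx.append(i)
    return idx


def fit_mixture_summary(grid: np.ndarray, density: np.ndarray,
                        max_components: int | None = None,
                        floor_frac: float = 0.05) -> list[MixtureComponent]:
    """Gaussian-mixture summary of a switch-time density.

    Local maxima above ``floor_frac`` of the global maximum seed one
    component each (means at the maxima); the parametric mixture curve is
    then fitted to the density by least squares on the grid.  Returns
    components ordered by mean; an (effectively) flat or empty density
    yields no components.
    """
    idx = _local_maxima(grid, density, floor_frac)
    if max_components is not None:
        idx = sorted(sorted(idx, key=lambda i: -density[i])[:max_components])
    if not idx:
        return []
    L = grid[-1]
    dx = grid[1] - grid[0]
    means0 = grid[idx]
    # initial sigma: half-width at half maximum of each peak, floored at dx
    sig0 = []
    for i in idx:
        half = 0.5 * density[i]
        left = i
        while left > 0 and density[left] > half:
            left -= 1
        right = i
        while right < density.size - 1 and density[right] > half:
            right += 1
        sig0.append(max(dx, 0.5 * (grid[right] - grid[left]) / 1.177))
    sig0 = np.asarray(sig0)
    w0 = np.clip(density[idx] * sig0 * np.sqrt(2 * np.pi), 1e-6, None)

    m = len(idx)

    def unpack(p):
        return p[:m], np.abs(p[m:2 * m]) + 1e-6, np.abs(p[2 * m:]) + 1e-12

    def curve(p):
        mu, sg, w = unpack(p)
        z = (grid[:, None] - mu[None, :]) / sg[None, :]
        comp = np.exp(-0.5 * z * z) / (np.sqrt(2 * np.pi) * sg[None, :])
        return comp @ w

    p0 = np.concatenate([means0, sig0, w0])
    res = least_squares(lambda p: curve(p) - density, p0, method="lm",
                        max_nfev=2000)
    mu, sg, w = unpack(res.x)
    comps = [MixtureComponent(float(mu[i]), float(sg[i]), float(w[i]))
             for i in range(m) if 0.0 < mu[i] < L]
    return sorted(comps, key=lambda cm: cm.mean)


def classify_on_off(trace: PosteriorTrace, thin: int = 1
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Split sampled switch times into on- and off-switch subsets.

    A switch is "on" when the transcription rate of the following regime
    exceeds the preceding one; ties count as off.  Returns
    (on_times, off_times) over post-burn-in iterations.
    """
    on, off = [], []
    for t, b_prev, b_next in trace.switch_events(thin=thin):
        (on if b_next > b_prev else off).append(t)
    return np.asarray(on), np.asarray(off)


def summarize_trace(trace: PosteriorTrace, grid_size: int = 512,
                    bandwidth: float | None = None, thin: int = 1,
                    max_components: int | None = None,
                    floor_frac: float = 0.05) -> SwitchDistribution:
    """Full switch-time summary of one gene's trace.

    Builds the whole/on/off densities with a common bandwidth, fits the
    Gaussian-mixture summary to the whole density, and records sample
    shares so the weighted on/off densities reconstruct the whole one.
    """
    grid = np.linspace(0.0, trace.L, grid_size)
    on_t, off_t = classify_on_off(trace, thin=thin)
    pooled = np.concatenate([on_t, off_t])
    n = pooled.size
    if n == 0:
        zero = np.zeros_like(grid)
        return SwitchDistribution(grid, zero, zero.copy(), zero.copy(),
                                  0.0, 0.0, [], 0, 0, 0, trace.L)
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(pooled)
    raw_on = _kde_on_grid(on_t, grid, h)
    raw_off = _kde_on_grid(off_t, grid, h)
    raw_whole = (on_t.size * raw_on + off_t.size * raw_off) / n
    whole, i_whole = _normalize(grid, raw_whole)
    on_d, i_on = _normalize(grid, raw_on)
    off_d, i_off = _normalize(grid, raw_off)
    on_w = (on_t.size / n) * (i_on / i_whole) if i_whole > 0 else 0.0
    off_w = (off_t.size / n) * (i_off / i_whole) if i_whole > 0 else 0.0
    kmax_seen = int(trace.post_burn("k").max())
    comps = fit_mixture_summary(
        grid, whole,
        max_components=(max_components if max_components is not None
                        else kmax_seen),
        floor_frac=floor_frac)
    return SwitchDistribution(grid, whole, on_d, off_d, on_w, off_w, comps,
                              n, on_t.size, off_t.size, trace.L)
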