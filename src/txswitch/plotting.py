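"""Plot helpers: fitted trajectories, switch-time densities, enrichment
heatmaps.  All functions return the matplotlib Axes they drew on."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_fit(results, ax=None, dark_periods=()):
    """Data, posterior-mean fitted curve and two-sigma switch bands."""
    ax = _get_ax(ax)
    series = results.model.series
    for r in range(series.n_replicates):
        ax.plot(series.times, series.values[r], "o", color="0.4", ms=4,
                alpha=0.6)
    grid = np.linspace(0.0, series.L, 400)
    try:
        ax.plot(grid, results.posterior_mean_curve(grid), "r-", lw=1.5,
                label="posterior-mean fit")
    except Exception:
        pass  # rank-deficient representative config: show data only
    for c in results.switch_distribution.components:
        lo, hi = c.band
        ax.axvspan(max(lo, 0.0), min(hi, series.L), color="tab:blue",
                   alpha=0.15)
        ax.axvline(c.mean, color="tab:blue", lw=0.8)
    for lo, hi in dark_periods:
        ax.axvspan(lo, hi, color="0.8", alpha=0.4, zorder=0)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("expression")
    ax.set_title(f"{series.gene_id} ({series.experiment_id})")
    return ax


def plot_switch_density(sd, ax=None):
    """Whole/on/off switch-time densities with mixture means marked."""
    ax = _get_ax(ax)
    ax.plot(sd.grid, sd.density, "k-", label="all switches")
    ax.plot(sd.grid, sd.on_weight * sd.on_density, "-", color="tab:green",
            label="on")
    ax.plot(sd.grid, sd.off_weight * sd.off_density, "--", color="tab:red",
            label="off")
    for c in sd.components:
        ax.axvline(c.mean, color="tab:blue", lw=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax


def plot_enrichment_heatmap(heatmap_table, significant=None, ax=None):
    """Motif-by-cluster proportion heatmap (population column included)."""
    ax = _get_ax(ax)
    vals = heatmap_table.to_numpy(dtype=float)
    im = ax.imshow(vals, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(heatmap_table.shape[1]))
    ax.set_xticklabels(heatmap_table.columns)
    ax.set_yticks(range(heatmap_table.shape[0]))
    ax.set_yticklabels(heatmap_table.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="motif proportion")
    if significant is not None:
        for (mi, ci) in significant:
            ax.text(ci, mi, "*", ha="center", va="center", color="w")
    return ax
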