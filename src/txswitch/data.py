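"""Containers and file I/O for time-series expression data.

The package works on one gene at a time: an :class:`ExpressionSeries` holds
the observation times (hours) and a replicate-by-time matrix of expression
values on the interval [0, L].  Missing cells are NaN; all operations count
only non-missing observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LONG_COLUMNS = ["gene_id", "experiment_id", "replicate", "time_h", "value"]


@dataclass
class ExpressionSeries:
    """One gene's observed time course in one experiment.

    Parameters
    ----------
    gene_id, experiment_id : str
        Identifiers carried through to outputs.
    times : array-like of float
        Strictly increasing observation times in hours, all within [0, L].
    values : array-like, shape (R, T)
        Expression values, one row per replicate, aligned to ``times``.
        NaN marks a missing cell.  Units are arbitrary but assumed
        proportional to mRNA concentration.
    L : float, optional
        Length of the observation interval in hours.  Defaults to the last
        observation time.
    """

    gene_id: str
    experiment_id: str
    times: np.ndarray
    values: np.ndarray
    L: float | None = None

    # flattened non-missing views, built once
    _t: np.ndarray = field(init=False, repr=False)
    _y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[1] != self.times.size:
            raise ValueError(
                f"values has {self.values.shape[1]} columns but there are "
                f"{self.times.size} times"
            )
        if self.L is None:
            self.L = float(self.times[-1])
        self.L = float(self.L)
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.times[0] < 0 or self.times[-1] > self.L:
            raise ValueError("times must lie within [0, L]")
        mask = np.isfinite(self.values)
        if mask.sum() < 3:
            raise ValueError("need at least 3 non-missing observations")
        tiled = np.broadcast_to(self.times, self.values.shape)
        self._t = tiled[mask].astype(float)
        self._y = self.values[mask].astype(float)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        """Count of non-missing cells across all replicates."""
        return self._t.size

    @property
    def stacked_times(self) -> np.ndarray:
        """Times of all non-missing cells, replicates concatenated."""
        return self._t

    @property
    def stacked_values(self) -> np.ndarray:
        """Values of all non-missing cells, aligned to stacked_times."""
        return self._y

    def replicate_mean(self) -> np.ndarray:
        """Per-timepoint mean over non-missing replicates."""
        return np.nanmean(self.values, axis=0)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_replicates):
            for j, t in enumerate(self.times):
                v = self.values[r, j]
                if np.isfinite(v):
                    rows.append((self.gene_id, self.experiment_id, r, t, v))
        return pd.DataFrame(rows, columns=LONG_COLUMNS)


def read_expression_long(path_or_df, sep: str = ",") -> list[ExpressionSeries]:
    """Read a long-format expression table into ExpressionSeries objects.

    Expects columns gene_id, experiment_id, replicate, time_h, value; one
    series is produced per (gene_id, experiment_id) pair, ordered as first
    encountered.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep=sep, comment="#")
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long-format table missing columns: {sorted(missing)}")
    out = []
    for (gene, exp), grp in df.groupby(["gene_id", "experiment_id"], sort=False):
        times = np.sort(grp["time_h"].unique())
        reps = sorted(grp["replicate"].unique())
        mat = np.full((len(reps), len(times)), np.nan)
        tix = {t: j for j, t in enumerate(times)}
        rix = {r: i for i, r in enumerate(reps)}
        for _, row in grp.iterrows():
            mat[rix[row["replicate"]], tix[row["time_h"]]] = row["value"]
        out.append(ExpressionSeries(str(gene), str(exp), times, mat))
    return out


def read_expression_wide(path_or_df, gene_id: str = "gene",
                         experiment_id: str = "E", sep: str = ",") -> ExpressionSeries:
    """Convenience reader: wide table with a time_h column and one column
    per replicate."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep=sep, comment="#")
    if "time_h" not in df.columns:
        raise ValueError("wide-format table needs a time_h column")
    times = df["time_h"].to_numpy(dtype=float)
    vals = df.drop(columns="time_h").to_numpy(dtype=float).T
    return ExpressionSeries(gene_id, experiment_id, times, vals)


def write_expression_long(series_list, path, sep: str = ",") -> None:
    df = pd.concat([s.to_long() for s in series_list], ignore_index=True)
    df.to_csv(path, sep=sep, index=False)
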