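"""Switch-time-based gene clustering and promoter-motif enrichment.

Pairwise dissimilarity between genes is the symmetric Kullback-Leibler
distance between their switch-time densities (whole, or on/off subsets
summed).  Negated distances form similarity matrices that can be
standardized and linearly combined — across experiments, with an
expression-profile similarity, or with motif co-occurrence — and
clustered by affinity propagation.  Cluster-level motif over-representation
is scored by the hypergeometric tail with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SimilarityMatrix",
    "symmetric_kl",
    "sd_distance_matrix",
    "similarity_from_distances",
    "standardize_similarity",
    "combine_similarities",
    "motif_cooccurrence_similarity",
    "expression_profile_similarity",
    "cluster_affinity_propagation",
    "validate_motif_table",
    "motif_enrichment",
]

KL_FLOOR = 1e-10


@dataclass
class SimilarityMatrix:
    """Symmetric gene-by-gene similarity scores.

    ``provenance`` records the source (``SD-whole``, ``SD-on+off``,
    ``expression-SSE``, ``motif`` or ``combined``); ``weights`` the linear
    combination used, if any.
    """

    gene_ids: list
    matrix: np.ndarray
    provenance: str = ""
    weights: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.gene_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match gene ids")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene ids must be unique")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids,
                            columns=self.gene_ids)


def symmetric_kl(p: np.ndarray, q: np.ndarray, grid: np.ndarray,
                 eps: float = KL_FLOOR) -> float:
    """Symmetric Kullback-Leibler distance KL(p||q) + KL(q||p).

    Both densities must be normalized on the same grid; a floor ``eps`` is
    added before taking logs (KDE densities vanish at domain edges).
    Trapezoid quadrature; non-negative, zero iff p == q on the grid.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != grid.shape or q.shape != grid.shape:
        raise ValueError("densities and grid must share one shape")
    log_ratio = np.log(p + eps) - np.log(q + eps)
    val = float(np.trapezoid((p - q) * log_ratio, grid))
    return max(val, 0.0)


def sd_distance_matrix(distributions: dict, which: str = "whole") -> pd.DataFrame:
    """Pairwise symmetric-KL distances between genes' switch densities.

    ``distributions`` maps gene id -> SwitchDistribution.  ``which`` is
    ``whole``, ``on``, ``off`` or ``on+off`` (sum of the separate on and
    off distances — the variant that groups genes whose expression is in
    phase, not merely switching at the same times).
    """
    genes = list(distributions)
    n = len(genes)
    grids = [distributions[g].grid for g in genes]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("switch distributions must share a common grid")
    grid = grids[0]

    def dens(g, kind):
        d = distributions[g]
        return {"whole": d.density, "on": d.on_density,
                "off": d.off_density}[kind]

    kinds = ["on", "off"] if which == "on+off" else [which]
    D = np.zeros((n, n))
    for kind in kinds:
        for i in range(n):
            for j in range(i + 1, n):
                d = symmetric_kl(dens(genes[i], kind), dens(genes[j], kind), grid)
                D[i, j] += d
                D[j, i] += d
    return pd.DataFrame(D, index=genes, columns=genes)


def similarity_from_distances(distances: pd.DataFrame,
                              provenance: str = "") -> SimilarityMatrix:
    """Similarity = -distance (affinity propagation consumes similarities).

    The diagonal is left at 0 = maximal similarity; the clustering step
    overrides it with the preference.
    """
    D = np.asarray(distances, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    return SimilarityMatrix(list(distances.index), -D, provenance=provenance)


def standardize_similarity(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Scale off-diagonal entries to median 0 and MAD 1.

    Puts heterogeneous scores (KL distances, motif co-occurrence, SSE) on
    a common scale before linear combination.
    """
    M = sim.matrix.copy()
    n = M.shape[0]
    off = M[~np.eye(n, dtype=bool)]
    med = np.median(off)
    mad = np.median(np.abs(off - med))
    if mad <= 0:
        mad = 1.0
    M = (M - med) / mad
    np.fill_diagonal(M, 0.0)
    return SimilarityMatrix(sim.gene_ids, M, provenance=sim.provenance)


def combine_similarities(sims: list, weights=None,
                         standardize: bool = True) -> SimilarityMatrix:
    """Weighted linear combination of similarity matrices.

    All inputs must cover the same genes in the same order; by default
    each is standardized first and weights are equal.
    """
    if not sims:
        raise ValueError("no similarity matrices supplied")
    base = sims[0].gene_ids
    for s in sims[1:]:
        if s.gene_ids != base:
            extra = set(s.gene_ids) ^ set(base)
            raise ValueError(f"gene sets differ; offending ids: {sorted(extra)[:10]}")
    if weights is None:
        weights = [1.0 / len(sims)] * len(sims)
    if len(weights) != len(sims):
        raise ValueError("one weight per matrix required")
    mats = [standardize_similarity(s).matrix if standardize else s.matrix
            for s in sims]
    M = sum(w * m for w, m in zip(weights, mats))
    prov = "combined(" + "+".join(s.provenance or "?" for s in sims) + ")"
    return SimilarityMatrix(list(base), M, provenance=prov,
                            weights=list(weights))


def validate_motif_table(motifs: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-by-motif binary presence table."""
    vals = motifs.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("motif table entries must be 0/1")
    empty = motifs.columns[vals.sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"motifs present in no gene: {list(empty)}")
    return motifs


def motif_cooccurrence_similarity(motifs: pd.DataFrame,
                                  method: str = "jaccard") -> SimilarityMatrix:
    """Gene-gene similarity from shared promoter motifs.

    ``jaccard`` (default): |shared| / |union|, 0 when both genes carry no
    motif.  ``count``: raw number of shared motifs.
    """
    validate_motif_table(motifs)
    X = motifs.to_numpy(dtype=float)
    shared = X @ X.T
    if method == "count":
        M = shared
    elif method == "jaccard":
        totals = X.sum(axis=1)
        union = totals[:, None] + totals[None, :] - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(union > 0, shared / np.maximum(union, 1e-300), 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SimilarityMatrix(list(motifs.index), M, provenance="motif")


def expression_profile_similarity(series_list) -> SimilarityMatrix:
    """Similarity from normalized expression profiles (negated SSE).

    Profiles are replicate means, standardized per gene to zero mean and
    unit variance over time; the distance between two genes is the sum of
    squared differences of these normalized profiles.
    """
    times0 = series_list[0].times
    for s in series_list[1:]:
        if s.times.shape != times0.shape or not np.allclose(s.times, times0):
            raise ValueError("series must share a common time grid")
    profiles = []
    for s in series_list:
        prof = s.replicate_mean()
        sd = prof.std()
        profiles.append((prof - prof.mean()) / (sd if sd > 0 else 1.0))
    P = np.asarray(profiles)
    sq = (P ** 2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * P @ P.T
    np.fill_diagonal(D, 0.0)
    genes = [s.gene_id for s in series_list]
    return SimilarityMatrix(genes, -np.maximum(D, 0.0),
                            provenance="expression-SSE")


@dataclass
class ClusterResult:
    labels: pd.Series
    exemplars: list
    converged: bool
    n_clusters: int


def cluster_affinity_propagation(sim: SimilarityMatrix,
                                 preference: float | None = None,
                                 damping: float = 0.9, max_iter: int = 1000,
                                 seed: int = 0) -> ClusterResult:
    """Affinity-propagation clustering of a similarity matrix.

    The number of clusters emerges from ``preference`` (default: median
    similarity).  Non-convergence returns the current labels with
    ``converged=False`` and a warning.
    """
    M = sim.matrix
    if not np.all(np.isfinite(M)):
        raise ValueError("similarities must be finite")
    n = M.shape[0]
    if n == 1:
        return ClusterResult(pd.Series([0], index=sim.gene_ids),
                             [sim.gene_ids[0]], True, 1)
    ap = AffinityPropagation(affinity="precomputed", preference=preference,
                             damping=damping, max_iter=max_iter,
                             random_state=seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ap.fit(M)
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
    labels = ap.labels_.copy()
    if not converged or (labels < 0).any():
        if not converged:
            warnings.warn("affinity propagation did not converge",
                          RuntimeWarning, stacklevel=2)
        if (labels < 0).any():
            labels = np.zeros(n, dtype=int)
    exemplars = ([sim.gene_ids[i] for i in ap.cluster_centers_indices_]
                 if ap.cluster_centers_indices_ is not None
                 and len(ap.cluster_centers_indices_) else [])
    return ClusterResult(pd.Series(labels, index=sim.gene_ids), exemplars,
                         converged, int(len(np.unique(labels))))


def hypergeom_pvalue(n_population: int, n_motif: int, n_cluster: int,
                     n_overlap: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, m, n): over-representation tail."""
    return float(hypergeom.sf(n_overlap - 1, n_population, n_motif, n_cluster))


def motif_enrichment(labels: pd.Series, motifs: pd.DataFrame,
                     fdr_level: float = 0.05) -> pd.DataFrame:
    """Per (cluster, motif) over-representation with BH FDR control.

    The population is the labelled gene set; for every cluster and motif
    the hypergeometric upper tail compares the cluster's motif count
    against the population count.  Benjamini-Hochberg is applied across
    all (cluster, motif) pairs at ``fdr_level``.

    Returns a tidy frame: cluster, motif, cluster_size, count, proportion,
    population_proportion, p_value, q_value, significant.
    """
    validate_motif_table(motifs)
    missing = set(labels.index) - set(motifs.index)
    if missing:
        raise ValueError(f"genes missing from motif table: {sorted(missing)[:10]}")
    motifs = motifs.loc[labels.index]
    N = len(labels)
    rows = []
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        n = len(members)
        if n == 0:
            continue
        for motif in motifs.columns:
            m = int(motifs[motif].sum())
            x = int(motifs.loc[members, motif].sum())
            rows.append({"cluster": cl, "motif": motif, "cluster_size": n,
                         "count": x, "proportion": x / n,
                         "population_proportion": m / N,
                         "p_value": hypergeom_pvalue(N, m, n, x)})
    out = pd.DataFrame(rows)
    reject, qvals, _, _ = multipletests(out["p_value"], alpha=fdr_level,
                                        method="fdr_bh")
    out["q_value"] = qvals
    out["significant"] = reject
    return out


def enrichment_heatmap_table(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Motif-by-cluster proportion table with a population column 'P'."""
    pivot = enrichment.pivot(index="motif", columns="cluster",
                             values="proportion")
    pop = enrichment.groupby("motif")["population_proportion"].first()
    pivot["P"] = pop
    return pivot
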