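"""Symmetric-KL similarity, matrix combination, affinity propagation,
motif enrichment with BH control."""

import numpy as np
import pandas as pd
import pytest

import txswitch as tx
from txswitch.cluster import (SimilarityMatrix, enrichment_heatmap_table,
                              hypergeom_pvalue, standardize_similarity,
                              validate_motif_table)
from txswitch.summarize import SwitchDistribution


def gaussian(grid, mu, sigma):
    return np.exp(-0.5 * ((grid - mu) / sigma) ** 2) / (
        np.sqrt(2 * np.pi) * sigma)


def make_sd(grid, mu, sigma=1.5):
    dens = gaussian(grid, mu, sigma)
    dens /= np.trapezoid(dens, grid)
    return SwitchDistribution(grid, dens, dens.copy(), dens.copy(),
                              0.5, 0.5, [], 100, 50, 50, grid[-1])


class TestSymmetricKL:
    def test_identical_densities_zero(self):
        grid = np.linspace(0, 48, 300)
        p = gaussian(grid, 20, 2.0)
        assert tx.symmetric_kl(p, p, grid) == 0.0

    def test_gaussian_closed_form(self):
        """Symmetric KL between N(0,1) and N(1,1) is exactly
        (mu1 - mu2)^2 / sigma^2 = 1."""
        grid = np.linspace(-10, 11, 4000)
        p = gaussian(grid, 0.0, 1.0)
        q = gaussian(grid, 1.0, 1.0)
        val = tx.symmetric_kl(p, q, grid, eps=0.0)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_symmetry(self, rng):
        grid = np.linspace(0, 48, 300)
        p = gaussian(grid, 12, 2.0)
        q = gaussian(grid, 30, 4.0)
        assert tx.symmetric_kl(p, q, grid) == tx.symmetric_kl(q, p, grid)

    def test_nonnegative_premetric(self, rng):
        grid = np.linspace(0, 48, 200)
        for _ in range(10):
            p = gaussian(grid, rng.uniform(5, 43), rng.uniform(0.5, 5))
            q = gaussian(grid, rng.uniform(5, 43), rng.uniform(0.5, 5))
            assert tx.symmetric_kl(p, q, grid) >= 0.0

    def test_mismatched_grid_raises(self):
        grid = np.linspace(0, 48, 100)
        with pytest.raises(ValueError):
            tx.symmetric_kl(np.ones(100), np.ones(50), grid)


class TestSimilarityConstruction:
    def test_similarity_is_negated_distance(self):
        D = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        sim = tx.similarity_from_distances(D)
        assert sim.matrix[0, 1] == -2.0
        assert sim.matrix[0, 0] == 0.0  # self-similarity maximal

    def test_rank_order_reversed(self, rng):
        n = 6
        D = np.abs(rng.standard_normal((n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = [f"g{i}" for i in range(n)]
        sim = tx.similarity_from_distances(pd.DataFrame(D, ids, ids))
        iu = np.triu_indices(n, 1)
        assert np.array_equal(np.argsort(D[iu]), np.argsort(-sim.matrix[iu]))

    def test_nan_distance_raises(self):
        D = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            tx.similarity_from_distances(D)

    def test_sd_distance_on_off_sums_components(self):
        grid = np.linspace(0, 48, 200)
        sds = {"a": make_sd(grid, 10.0), "b": make_sd(grid, 30.0)}
        whole = tx.sd_distance_matrix(sds, which="whole")
        on = tx.sd_distance_matrix(sds, which="on")
        off = tx.sd_distance_matrix(sds, which="off")
        both = tx.sd_distance_matrix(sds, which="on+off")
        assert np.allclose(both, on + off)
        assert whole.loc["a", "b"] > 0


class TestCombination:
    def _sim(self, mat, ids=("a", "b", "c")):
        return SimilarityMatrix(list(ids), np.asarray(mat, float), "t")

    def test_single_matrix_weight_one_is_identity(self, rng):
        M = rng.standard_normal((3, 3))
        M = (M + M.T) / 2
        sim = self._sim(M)
        out = tx.combine_similarities([sim], weights=[1.0],
                                      standardize=False)
        assert np.allclose(out.matrix, M)

    def test_zero_weight_drops_matrix(self, rng):
        A = rng.standard_normal((3, 3))
        A = (A + A.T) / 2
        B = rng.standard_normal((3, 3))
        B = (B + B.T) / 2
        out = tx.combine_similarities([self._sim(A), self._sim(B)],
                                      weights=[1.0, 0.0], standardize=False)
        assert np.allclose(out.matrix, A)

    def test_gene_set_mismatch_names_offenders(self):
        A = self._sim(np.zeros((3, 3)))
        B = self._sim(np.zeros((3, 3)), ids=("a", "b", "x"))
        with pytest.raises(ValueError, match="x"):
            tx.combine_similarities([A, B])

    def test_standardization_median_zero_mad_one(self, rng):
        M = rng.standard_normal((8, 8)) * 7 + 3
        M = (M + M.T) / 2
        out = standardize_similarity(self._sim(M, ids=[f"g{i}"
                                                       for i in range(8)]))
        off = out.matrix[~np.eye(8, dtype=bool)]
        assert np.median(off) == pytest.approx(0.0, abs=1e-12)
        assert np.median(np.abs(off)) == pytest.approx(1.0, rel=1e-9)

    def test_self_combination_preserves_clustering(self, rng):
        sim = block_similarity(rng)
        base = tx.cluster_affinity_propagation(sim, seed=0).labels
        comb = tx.combine_similarities([sim, sim], weights=[0.3, 0.7],
                                       standardize=False)
        lab = tx.cluster_affinity_propagation(comb, seed=0).labels
        assert _same_partition(base, lab)


def _same_partition(a, b):
    m = {}
    for x, y in zip(a, b):
        if x in m and m[x] != y:
            return False
        m[x] = y
    return len(set(m.values())) == len(m)


def block_similarity(rng, n_blocks=3, size=8):
    n = n_blocks * size
    D = np.full((n, n), 10.0)
    for bl in range(n_blocks):
        idx = slice(bl * size, (bl + 1) * size)
        D[idx, idx] = 0.0
    D += 0.01 * np.abs(rng.standard_normal((n, n)))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = [f"g{i}" for i in range(n)]
    return tx.similarity_from_distances(pd.DataFrame(D, ids, ids))


class TestAffinityPropagation:
    def test_recovers_planted_blocks(self, rng):
        sim = block_similarity(rng)
        res = tx.cluster_affinity_propagation(sim, seed=0)
        assert res.converged
        assert res.n_clusters == 3
        labels = res.labels.to_numpy()
        for bl in range(3):
            assert len(set(labels[bl * 8:(bl + 1) * 8])) == 1

    def test_preference_sweep_monotone_trend(self, rng):
        sim = block_similarity(rng, n_blocks=4, size=6)
        counts = []
        for pref in [-0.5, -5.0, -50.0, -500.0]:
            res = tx.cluster_affinity_propagation(sim, preference=pref,
                                                  seed=0)
            counts.append(res.n_clusters)
        assert counts[-1] <= counts[0]
        assert min(counts) >= 1

    def test_single_gene_is_own_exemplar(self):
        sim = SimilarityMatrix(["solo"], np.zeros((1, 1)), "t")
        res = tx.cluster_affinity_propagation(sim)
        assert res.labels.tolist() == [0]
        assert res.exemplars == ["solo"]


class TestExpressionProfileSimilarity:
    def _series(self, gid, values, times=None):
        times = times if times is not None else np.arange(len(values), dtype=float)
        return tx.ExpressionSeries(gid, "e", times,
                                   np.asarray(values, float)[None, :])

    def test_identical_profiles_zero_distance(self):
        s = [self._series("a", [1, 2, 3, 1]), self._series("b", [1, 2, 3, 1])]
        sim = tx.expression_profile_similarity(s)
        assert sim.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profile_is_farthest(self):
        base = [1.0, 2.0, 3.0, 2.0, 1.0]
        s = [self._series("a", base),
             self._series("b", [-v for v in base]),
             self._series("c", [v + 0.1 for v in base])]
        sim = tx.expression_profile_similarity(s)
        pair_min = min(sim.matrix[0, 1], sim.matrix[0, 2], sim.matrix[1, 2])
        assert sim.matrix[0, 1] <= pair_min + 1e-9

    def test_hand_computed_sse(self):
        """Normalization off is approximated by comparing against the
        same z-scoring done by hand for 3-point profiles."""
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        expected = float(((za - zb) ** 2).sum())
        s = [self._series("a", a), self._series("b", b)]
        sim = tx.expression_profile_similarity(s)
        assert -sim.matrix[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_mismatched_grids_raise(self):
        s = [self._series("a", [1, 2, 3]),
             self._series("b", [1, 2, 3, 4])]
        with pytest.raises(ValueError):
            tx.expression_profile_similarity(s)


class TestMotifSimilarity:
    def test_jaccard_examples(self):
        motifs = pd.DataFrame(
            [[1, 1, 1, 0], [0, 1, 1, 1], [1, 1, 1, 0]],
            index=["A", "B", "C"], columns=list("wxyz"))
        sim = tx.motif_cooccurrence_similarity(motifs)
        assert sim.matrix[0, 1] == pytest.approx(2.0 / 4.0)
        assert sim.matrix[0, 2] == pytest.approx(1.0)

    def test_disjoint_vectors_zero(self):
        motifs = pd.DataFrame([[1, 0], [0, 1]], index=["A", "B"],
                              columns=["m1", "m2"])
        sim = tx.motif_cooccurrence_similarity(motifs)
        assert sim.matrix[0, 1] == 0.0

    def test_invalid_entries_rejected(self):
        motifs = pd.DataFrame([[2, 0], [0, 1]], index=["A", "B"],
                              columns=["m1", "m2"])
        with pytest.raises(ValueError):
            validate_motif_table(motifs)

    def test_empty_motif_rejected(self):
        motifs = pd.DataFrame([[1, 0], [1, 0]], index=["A", "B"],
                              columns=["m1", "m2"])
        with pytest.raises(ValueError):
            validate_motif_table(motifs)


class TestEnrichment:
    def test_exact_hypergeometric_tail(self):
        """All 5 genes of a cluster carry a motif present in 10 of 20:
        p = C(10,5)/C(20,5) = 252/15504."""
        assert hypergeom_pvalue(20, 10, 5, 5) == pytest.approx(
            252.0 / 15504.0, rel=1e-12)

    def test_null_proportion_not_flagged(self, rng):
        genes = [f"g{i}" for i in range(100)]
        labels = pd.Series([0] * 50 + [1] * 50, index=genes)
        presence = np.zeros((100, 1), dtype=int)
        presence[::2] = 1  # motif proportion identical in both clusters
        motifs = pd.DataFrame(presence, index=genes, columns=["m"])
        out = tx.motif_enrichment(labels, motifs)
        assert not out["significant"].any()
        assert (out["p_value"] > 0.3).all()

    def test_planted_enrichment_flagged(self, rng):
        genes = [f"g{i}" for i in range(60)]
        labels = pd.Series([0] * 20 + [1] * 40, index=genes)
        table, planted = tx.simulate_motif_table(
            labels, n_motifs=10, baseline_p=0.28,
            enriched={0: [0, 1]}, enriched_p=0.95, seed=5)
        out = tx.motif_enrichment(labels, table)
        flagged = set(map(tuple, out.loc[out["significant"],
                                         ["cluster", "motif"]].to_numpy()))
        assert set(planted) <= flagged

    def test_bh_matches_independent_stepup(self, rng):
        """BH flags are exactly {p_(i) <= (i/M) q} under the step-up rule,
        checked against a direct sort-based implementation."""
        genes = [f"g{i}" for i in range(40)]
        labels = pd.Series(rng.integers(0, 3, size=40), index=genes)
        table, _ = tx.simulate_motif_table(labels, n_motifs=8,
                                           baseline_p=0.4, seed=2)
        out = tx.motif_enrichment(labels, table, fdr_level=0.05)
        p = out["p_value"].to_numpy()
        M = p.size
        order = np.argsort(p)
        thresh = 0.05 * (np.arange(1, M + 1)) / M
        passed = p[order] <= thresh
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        expected = np.zeros(M, dtype=bool)
        expected[order[:k]] = True
        assert np.array_equal(out["significant"].to_numpy(), expected)

    def test_heatmap_table_has_population_column(self, rng):
        genes = [f"g{i}" for i in range(30)]
        labels = pd.Series(rng.integers(0, 2, size=30), index=genes)
        table, _ = tx.simulate_motif_table(labels, n_motifs=5, seed=3)
        out = tx.motif_enrichment(labels, table)
        heat = enrichment_heatmap_table(out)
        assert "P" in heat.columns
        pop = table.mean(axis=0)
        assert np.allclose(heat["P"].loc[pop.index], pop)

    def test_missing_gene_raises(self):
        labels = pd.Series([0, 1], index=["a", "b"])
        motifs = pd.DataFrame([[1]], index=["a"], columns=["m"])
        with pytest.raises(ValueError, match="b"):
            tx.motif_enrichment(labels, motifs)
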