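"""Dissimilarities, PCoA, Procrustes superimposition, PROTEST and the
random-species-subset null model."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from netnight.congruence import (
    DissimilarityResult,
    dissimilarity,
    null_model,
    pcoa,
    procrustes_r,
    protest,
    strategy_congruence,
)
from netnight.io import AbundanceMatrix


def matrix_from(counts, species=None, site="s1"):
    counts = np.asarray(counts)
    species = species or [f"sp{j}" for j in range(counts.shape[1])]
    index = pd.MultiIndex.from_tuples(
        [(site, f"n{i}") for i in range(counts.shape[0])], names=["site", "night"]
    )
    return AbundanceMatrix(pd.DataFrame(counts, index=index, columns=species))


class TestDissimilarity:
    def test_identical_rows_distance_zero(self):
        m = matrix_from([[1, 2, 0]] * 3)
        for metric in ("jaccard", "braycurtis"):
            d = dissimilarity(m, metric)
            assert np.allclose(d.distances, 0.0)

    def test_disjoint_rows_distance_one(self):
        m = matrix_from([[2, 0], [0, 3], [2, 0]])
        for metric in ("jaccard", "braycurtis"):
            d = dissimilarity(m, metric).distances
            assert d[0, 1] == pytest.approx(1.0)

    def test_plug_in_values(self):
        m = matrix_from([[2, 1, 0], [1, 1, 1], [1, 0, 0]])
        bc = dissimilarity(m, "braycurtis").distances
        assert bc[0, 1] == pytest.approx(1 / 3)
        jac = dissimilarity(m, "jaccard").distances
        assert jac[0, 1] == pytest.approx(1 / 3)

    def test_metrics_agree_on_binary_matrices_up_to_monotone_map(self, rng):
        """On 0/1 data Bray-Curtis reduces to the Sorensen index and
        Jaccard to its monotone transform J = 2·BC/(1+BC), so the two
        carry the same rank information about community overlap."""
        binary = (rng.random((6, 5)) < 0.5).astype(int)
        binary[binary.sum(axis=1) == 0, 0] = 1
        m = matrix_from(binary)
        jac = dissimilarity(m, "jaccard").distances
        bc = dissimilarity(m, "braycurtis").distances
        np.testing.assert_allclose(jac, 2 * bc / (1 + bc), atol=1e-12)

    def test_zero_rows_dropped_and_reported(self):
        m = matrix_from([[1, 1], [0, 0], [2, 0], [1, 2]])
        d = dissimilarity(m, "braycurtis")
        assert d.dropped_rows == [("s1", "n1")]
        assert len(d.row_labels) == 3
        assert not d.degenerate

    def test_degenerate_when_too_few_rows_remain(self):
        m = matrix_from([[1, 1], [0, 0], [0, 0]])
        assert dissimilarity(m, "jaccard").degenerate


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 2.0]])
        d = squareform(pdist(pts))
        res = pcoa(
            DissimilarityResult(d, list(range(4)), [], "euclidean"), n_axes=3
        )
        recovered = squareform(pdist(res.scores))
        np.testing.assert_allclose(recovered, d, atol=1e-8)

    def test_equilateral_triangle_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DissimilarityResult(d, list(range(3)), [], "unit"), n_axes=3)
        # simplex: two equal positive eigenvalues, third ~ 0 and dropped
        assert res.n_axes_used == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_duplicate_rows_coincide(self):
        m = matrix_from([[3, 1, 0], [3, 1, 0], [0, 2, 2], [1, 1, 1]])
        res = pcoa(dissimilarity(m, "braycurtis"), n_axes=3)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-8)

    def test_warns_when_fewer_positive_axes_than_requested(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning, match="positive PCoA axes"):
            pcoa(DissimilarityResult(d, list(range(3)), [], "unit"), n_axes=5)


class TestProcrustes:
    def config(self, rng, n=8, k=3):
        return rng.standard_normal((n, k))

    def test_self_comparison(self, rng):
        x = self.config(rng)
        m2, r = procrustes_r(x, x)
        assert m2 == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_invariance_under_similarity_transform(self, rng):
        x = self.config(rng, k=2)
        theta = np.radians(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        y = 2.0 * x @ rot + np.array([5.0, -3.0])
        m2, r = procrustes_r(x, y)
        assert r == pytest.approx(1.0, abs=1e-10)
        refl = y @ np.diag([1.0, -1.0])
        assert procrustes_r(x, refl)[1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_disparity(self, rng):
        x, y = self.config(rng), self.config(rng)
        _, _, disparity = scipy_procrustes(x, y)
        m2, _ = procrustes_r(x, y)
        assert m2 == pytest.approx(disparity, abs=1e-10)

    def test_matches_brute_force_rotation_scale_search(self, rng):
        """Independent oracle: minimise the residual over an explicit
        rotation-angle x reflection grid (optimal scale in closed form)
        for 2-D configurations."""
        x = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        y = x.copy()
        y[2] = [1.4, 0.7]  # displace one corner
        xs = (x - x.mean(0)) / np.linalg.norm(x - x.mean(0))
        ys = (y - y.mean(0)) / np.linalg.norm(y - y.mean(0))
        best = np.inf
        for theta in np.linspace(0, 2 * np.pi, 400_000, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            for flip in (1.0, -1.0):
                rot = np.array([[c, -s * flip], [s, c * flip]])
                scale = np.sum(xs * (ys @ rot))  # optimal s given rotation
                best = min(best, 1.0 - scale**2)
        m2, _ = procrustes_r(x, y)
        assert m2 == pytest.approx(best, abs=1e-6)

    def test_mismatched_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_r(self.config(rng, n=5), self.config(rng, n=6))


class TestProtest:
    def test_identical_configurations_minimal_p(self, rng):
        x = rng.standard_normal((20, 3))
        p = protest(x, x, n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_zero_permutations_rejected(self, rng):
        x = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            protest(x, x, n_perm=0)

    def test_unrelated_configurations_large_p(self, rng):
        x = rng.standard_normal((15, 3))
        y = rng.standard_normal((15, 3))
        p = protest(x, y, n_perm=99, seed=1)
        assert p > 0.05


class TestStrategyCongruence:
    def full(self, rng, n=12, s=8):
        counts = rng.poisson(1.5, size=(n, s))
        counts[:, 0] += 1
        return matrix_from(counts)

    def test_self_strategy_r_is_one(self, rng):
        full = self.full(rng)
        res = strategy_congruence(full, full, "braycurtis", n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-8)
        assert not res.degenerate

    def test_removing_all_zero_column_changes_nothing(self, rng):
        full = self.full(rng)
        full.data["ghost"] = 0
        trimmed = AbundanceMatrix(full.data.drop(columns="ghost"))
        res = strategy_congruence(full, trimmed, "jaccard", n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-8)

    def test_proportional_counts_full_congruence(self, rng):
        """Halving every count leaves Bray-Curtis distances unchanged, so
        a schedule sampling every night proportionally scores r = 1."""
        counts = 2 * rng.poisson(1.5, size=(10, 6)) + 2
        full = matrix_from(counts)
        half = matrix_from(counts // 2)
        res = strategy_congruence(full, half, "braycurtis", n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-8)

    def test_sparse_strategy_reported_degenerate(self, rng):
        full = self.full(rng, n=6)
        empty = AbundanceMatrix(full.data * 0)
        res = strategy_congruence(full, empty, "braycurtis", n_perm=9, seed=0)
        assert res.degenerate
        assert np.isnan(res.r)


class TestNullModel:
    def full(self, rng, n=15, s=10):
        counts = rng.poisson(2.0, size=(n, s))
        counts[:, 0] += 1
        return matrix_from(counts)

    def test_all_species_draws_are_perfect(self, rng):
        full = self.full(rng)
        s = int((full.data.sum(axis=0) > 0).sum())
        null = null_model(full, s, n_draws=5, metric="braycurtis", seed=0)
        ok = null.draws[~null.draws["failed"]]
        assert np.allclose(ok["r"], 1.0, atol=1e-8)

    def test_r_increases_with_k_on_average(self, rng):
        from scipy.stats import spearmanr

        full = self.full(rng, n=20, s=12)
        ks = [3, 5, 7, 9, 11]
        null = null_model(full, ks, n_draws=150, metric="braycurtis", seed=1)
        ok = null.draws[~null.draws["failed"]]
        means = ok.groupby("k")["r"].mean()
        rho, _ = spearmanr(means.index, means.to_numpy())
        assert rho > 0.8

    def test_k_out_of_range_rejected(self, rng):
        full = self.full(rng)
        with pytest.raises(ValueError):
            null_model(full, 1, n_draws=2)

    def test_percentile_uses_midranks(self):
        draws = pd.DataFrame({"k": [5] * 4, "r": [0.2, 0.4, 0.4, 0.8], "failed": False})
        from netnight.congruence import NullCurve

        null = NullCurve("matched-k", draws, 4, 0)
        assert null.percentile_of(0.4) == pytest.approx(0.25 + 0.25)
        assert null.percentile_of(0.9) == 1.0
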