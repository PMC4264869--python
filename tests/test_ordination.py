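"""Between-group PCA, scaled two-block PLS, and permutation tests."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from gmia.ordination import (BetweenGroupPCA, DataBlock, ScaledPLS,
                             between_group_pca, eigenimage_render,
                             permutation_test, scaled_pls,
                             shape_reconstruction)
from gmia.texture import TextureMap, map_from_vector

from _oracles import bgpca_dense_oracle, pls_dense_oracle


def make_block(rng, n=18, p=6, g=3, kind="shape", shift=1.0):
    labels = np.repeat(np.arange(g), n // g)
    X = rng.normal(size=(n, p))
    for i in range(g):
        X[labels == i] += shift * rng.normal(size=p)
    return DataBlock(X, kind, labels)


class TestBetweenGroupPCA:
    def test_two_groups_single_axis_is_mean_difference(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 6 + [1] * 6)
        X = rng.normal(size=(12, 5))
        X[labels == 1] += [2.0, -1.0, 0.5, 0.0, 0.0]
        block = DataBlock(X, "shape", labels)
        res = between_group_pca(block, d=1)
        diff = X[labels == 1].mean(0) - X[labels == 0].mean(0)
        axis = res.axes[:, 0]
        cos = abs(diff @ axis) / np.linalg.norm(diff)
        assert cos == pytest.approx(1.0)  # axis collinear with mean difference
        sep = np.linalg.norm(res.group_mean_scores[1] - res.group_mean_scores[0])
        assert sep == pytest.approx(np.linalg.norm(diff), abs=1e-10)

    def test_group_mean_distances_preserved_exactly(self):
        """In the full g-1 dimensions the projected group means keep their
        pairwise Euclidean distances — the defining exactness property."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            block = make_block(rng, n=21, p=40, g=3)
            res = between_group_pca(block)  # d = g - 1 = 2
            groups, means = np.unique(block.group_labels), None
            means = np.stack([block.matrix[block.group_labels == g].mean(0)
                              for g in groups])
            np.testing.assert_allclose(pdist(res.group_mean_scores),
                                       pdist(means), atol=1e-8)

    def test_matches_dense_oracle_on_small_matrix(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        labels = np.array([0, 0, 1, 1, 2, 2])
        block = DataBlock(X, "shape", labels)
        res = between_group_pca(block)
        axes_o, scores_o, mean_scores_o = bgpca_dense_oracle(X, labels, 2)
        for j in range(2):  # axes defined up to sign
            sign = np.sign(axes_o[:, j] @ res.axes[:, j])
            np.testing.assert_allclose(res.axes[:, j], sign * axes_o[:, j],
                                       atol=1e-10)
            np.testing.assert_allclose(res.scores[:, j],
                                       sign * scores_o[:, j], atol=1e-10)
            np.testing.assert_allclose(res.group_mean_scores[:, j],
                                       sign * mean_scores_o[:, j], atol=1e-10)

    def test_loadings_orthonormal_and_variance_fractions_valid(self):
        rng = np.random.default_rng(3)
        block = make_block(rng, n=24, p=10, g=4)
        res = between_group_pca(block)
        gram = res.axes.T @ res.axes
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-10)
        assert ((res.variance_explained >= 0)
                & (res.variance_explained <= 1)).all()

    def test_dimension_and_group_errors(self):
        rng = np.random.default_rng(4)
        block = make_block(rng, g=3)
        with pytest.raises(ValueError, match="n_components"):
            between_group_pca(block, d=3)
        with pytest.raises(ValueError, match="labels"):
            BetweenGroupPCA().fit(block.matrix)

    def test_transform_matches_fit_scores(self):
        rng = np.random.default_rng(5)
        block = make_block(rng)
        est = BetweenGroupPCA().fit(block.matrix, block.group_labels)
        np.testing.assert_allclose(est.transform(block.matrix), est.scores_,
                                   atol=1e-12)


class TestEigenimages:
    def _tiny_result(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.3, 0.7, (3, 16))  # 3 singleton groups, 4x4 images
        labels = np.array([0, 1, 2])
        block = DataBlock(X, "texture", labels)
        res = between_group_pca(block)
        index_map = np.array([(r, c) for r in range(4) for c in range(4)])
        mean = TextureMap(grid=X.mean(0).reshape(4, 4), kind="mean",
                          mask=np.ones((4, 4), bool))
        return X, res, mean, index_map

    def test_score_zero_returns_mean(self):
        _, res, mean, index_map = self._tiny_result()
        out = eigenimage_render(res, 0, 0.0, mean, index_map)
        np.testing.assert_allclose(out.grid, mean.grid, atol=1e-12)
        assert out.clip_fraction == 0.0

    def test_symmetry_about_mean(self):
        _, res, mean, index_map = self._tiny_result()
        up = eigenimage_render(res, 0, 0.05, mean, index_map)
        down = eigenimage_render(res, 0, -0.05, mean, index_map)
        np.testing.assert_allclose(up.grid - mean.grid,
                                   mean.grid - down.grid, atol=1e-12)

    def test_full_rank_reconstruction_restores_specimen(self):
        """With singleton groups the g-1 axes span the centered data, so a
        specimen is exactly recovered from its own scores."""
        X, res, mean, index_map = self._tiny_result()
        i = 1
        recon = res.center.copy()
        for ax in range(res.axes.shape[1]):
            recon = recon + res.scores[i, ax] * res.axes[:, ax]
        np.testing.assert_allclose(recon, X[i], atol=1e-8)

    def test_inconsistent_index_map_raises(self):
        _, res, mean, index_map = self._tiny_result()
        with pytest.raises(ValueError, match="index map"):
            eigenimage_render(res, 0, 1.0, mean, index_map[:-2])


class TestScaledPLS:
    def test_identical_blocks_give_first_pc(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2])
        res = ScaledPLS(n_components=1).fit(X, X.copy())
        Xc = X - X.mean(0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = vt[0]
        u = res.x_loadings_[:, 0]
        assert abs(abs(u @ pc1) - 1.0) < 1e-8
        np.testing.assert_allclose(res.x_loadings_, res.y_loadings_,
                                   atol=1e-8)
        var_along = Xc @ pc1
        assert res.covariances_[0] == pytest.approx(
            var_along.var(ddof=1), rel=1e-8)

    def test_toy_blocks_match_dense_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 3))
        Y = 0.5 * X[:, :2] + 0.1 * rng.normal(size=(8, 2))
        res = ScaledPLS(n_components=2).fit(X, Y)
        u_o, v_o, sigma_o = pls_dense_oracle(X, Y)
        s = np.sign(u_o @ res.x_loadings_[:, 0])
        np.testing.assert_allclose(res.x_loadings_[:, 0], s * u_o, atol=1e-8)
        np.testing.assert_allclose(res.y_loadings_[:, 0], s * v_o, atol=1e-8)
        assert res.covariances_[0] == pytest.approx(sigma_o, abs=1e-8)

    def test_dimension1_covariance_is_maximal(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 6))
        Y = X @ rng.normal(size=(6, 4)) + 0.5 * rng.normal(size=(25, 4))
        res = ScaledPLS(n_components=1).fit(X, Y)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        best = res.covariances_[0]
        for _ in range(1000):
            u = rng.normal(size=6); u /= np.linalg.norm(u)
            v = rng.normal(size=4); v /= np.linalg.norm(v)
            cov = (Xc @ u) @ (Yc @ v) / (len(X) - 1)
            assert cov <= best + 1e-10

    def test_deflation_gives_orthogonal_loadings(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 7))
        Y = rng.normal(size=(20, 5)) + X[:, :5]
        res = ScaledPLS(n_components=3).fit(X, Y)
        np.testing.assert_allclose(res.x_loadings_.T @ res.x_loadings_,
                                   np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.y_loadings_.T @ res.y_loadings_,
                                   np.eye(3), atol=1e-10)

    def test_loadings_unit_norm(self):
        rng = np.random.default_rng(11)
        res = ScaledPLS(n_components=2).fit(rng.normal(size=(15, 4)),
                                            rng.normal(size=(15, 6)))
        np.testing.assert_allclose((res.x_loadings_ ** 2).sum(0), 1.0,
                                   atol=1e-10)
        np.testing.assert_allclose((res.y_loadings_ ** 2).sum(0), 1.0,
                                   atol=1e-10)

    def test_independent_blocks_have_small_covariance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200, 5))
        Y = rng.normal(size=(200, 5))
        res = ScaledPLS(n_components=1).fit(X, Y)
        # null PLS covariance scales like 1/sqrt(n); compare against a
        # permutation quantile of the same statistic
        perm_covs = []
        for _ in range(100):
            Yp = Y[rng.permutation(200)]
            perm_covs.append(ScaledPLS(n_components=1).fit(X, Yp)
                             .covariances_[0])
        assert res.covariances_[0] < np.quantile(perm_covs, 0.99)

    def test_texture_scale_propagates_to_scaling_factors(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 4))
        Y = X @ rng.normal(size=(4, 3)) + 0.3 * rng.normal(size=(20, 3))
        r1 = ScaledPLS(n_components=2).fit(X, Y)
        c = 37.0
        r2 = ScaledPLS(n_components=2).fit(X, c * Y)
        # major-axis slopes are scale-equivariant up to the (small) tilt of
        # the principal axis; exact proportionality holds only in the limit
        # of perfectly correlated scores
        np.testing.assert_allclose(r2.scaling_factors_,
                                   c * r1.scaling_factors_, rtol=0.05)
        # joint score geometry stays similar: correlation per dimension ~ 1
        for dim in range(2):
            r = np.corrcoef(r2.joint_scores_[:, dim],
                            r1.joint_scores_[:, dim])[0, 1]
            assert r > 0.999

    def test_shape_and_texture_scores_positively_associated(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 4))
        Y = -X @ rng.normal(size=(4, 3)) + 0.2 * rng.normal(size=(20, 3))
        res = ScaledPLS(n_components=1).fit(X, Y)
        assert res.x_scores_[:, 0] @ res.y_scores_[:, 0] >= 0
        assert res.scaling_factors_[0] >= 0

    def test_input_validation(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError, match="same specimens"):
            ScaledPLS().fit(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            ScaledPLS().fit(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestPermutationTest:
    def test_huge_separation_gives_smallest_p(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 4))
        X[6:] += 1e3
        block = DataBlock(X, "shape", np.array([0] * 6 + [1] * 6))
        p, stat = permutation_test(block, 0, 1, n_perm=99, seed=0)
        assert p == pytest.approx(1.0 / 100.0)
        assert stat > 1e3 - 10

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(6, 3))
        X[3:] += 0.8
        labels = np.array([0, 0, 0, 1, 1, 1])
        block = DataBlock(X, "shape", labels)
        p, observed = permutation_test(block, 0, 1, method="exact")
        # oracle: enumerate all 20 splits with itertools directly
        stats = []
        for combo in combinations(range(6), 3):
            a = X[list(combo)]
            b = X[[i for i in range(6) if i not in combo]]
            stats.append(np.linalg.norm(a.mean(0) - b.mean(0)))
        expected = sum(s >= observed - 1e-12 for s in stats) / 20.0
        assert p == pytest.approx(expected)
        assert len(stats) == 20

    def test_p_value_bounds_and_reproducibility(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(10, 3))
        block = DataBlock(X, "shape", np.array([0] * 5 + [1] * 5))
        p1, _ = permutation_test(block, 0, 1, n_perm=49, seed=7)
        p2, _ = permutation_test(block, 0, 1, n_perm=49, seed=7)
        assert p1 == p2
        assert 1.0 / 50.0 <= p1 <= 1.0

    def test_empty_group_and_bad_nperm_raise(self):
        block = DataBlock(np.zeros((4, 2)), "shape", np.array([0, 0, 0, 0]))
        with pytest.raises(ValueError, match="non-empty"):
            permutation_test(block, 0, 1)
        block2 = DataBlock(np.zeros((4, 2)), "shape", np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(block2, 0, 1, n_perm=0)


class TestShapeReconstruction:
    def _result(self):
        rng = np.random.default_rng(19)
        shapes = rng.normal(size=(3, 5, 2)) * 0.1 + np.linspace(
            0, 1, 10).reshape(5, 2)
        X = shapes.reshape(3, -1)
        block = DataBlock(X, "shape", np.array([0, 1, 2]))
        return X, between_group_pca(block)

    def test_score_zero_is_mean_shape(self):
        _, res = self._result()
        mean_shape = res.center.reshape(5, 2)
        out = shape_reconstruction(res, 0, 0.0, mean_shape)
        np.testing.assert_allclose(out, mean_shape, atol=1e-12)

    def test_symmetry_about_mean(self):
        _, res = self._result()
        mean_shape = res.center.reshape(5, 2)
        up = shape_reconstruction(res, 1, 0.3, mean_shape)
        down = shape_reconstruction(res, 1, -0.3, mean_shape)
        np.testing.assert_allclose(up - mean_shape, mean_shape - down,
                                   atol=1e-12)

    def test_full_rank_reconstruction_recovers_specimen(self):
        X, res = self._result()
        mean_shape = res.center.reshape(5, 2)
        recon = mean_shape
        for ax in range(res.axes.shape[1]):
            recon = shape_reconstruction(res, ax, res.scores[2, ax], recon)
        np.testing.assert_allclose(recon.ravel(), X[2], atol=1e-8)

    def test_dimension_mismatch_raises(self):
        _, res = self._result()
        with pytest.raises(ValueError, match="mean shape"):
            shape_reconstruction(res, 0, 1.0, np.zeros((4, 2)))
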