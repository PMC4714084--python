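"""DAPC: PCA against an eigendecomposition oracle, posterior membership
probabilities against sklearn's homoscedastic LDA, and cross-validated PC
retention (determinism, null behaviour, recovery)."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from wingmorph import dapc


class TestCenterFeatures:
    def test_column_means_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 5, (20, 6))
        centered, means = dapc.center_features(x)
        assert np.allclose(centered.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(means, x.mean(axis=0))
        again, _ = dapc.center_features(centered)
        assert np.allclose(again, centered, atol=1e-12)

    def test_repeated_row_gives_zeros(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1))
        centered, _ = dapc.center_features(x)
        assert np.allclose(centered, 0, atol=1e-12)

    def test_scaling_constant_column_errors(self):
        x = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="constant"):
            dapc.center_features(x, scale=True)


class TestPca:
    def test_collinear_points_rank_one(self):
        t = np.linspace(-1, 1, 10)
        x = np.column_stack([t, 2 * t])
        res = dapc.pca(x, r=1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one_over_full_rank(self):
        rng = np.random.default_rng(1)
        x, _ = dapc.center_features(rng.standard_normal((12, 5)))
        res = dapc.pca(x)
        frac = res.explained_variance_fraction
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(frac) <= 1e-12)  # non-increasing

    def test_matches_covariance_eigendecomposition(self):
        # independent oracle: dense eigensolver on the covariance matrix
        rng = np.random.default_rng(2)
        x, _ = dapc.center_features(rng.standard_normal((10, 6)))
        res = dapc.pca(x)
        evals = np.sort(np.linalg.eigvalsh(x.T @ x / 1.0))[::-1]
        sv2 = (res.scores**2).sum(axis=0)
        assert np.allclose(sv2, evals[: len(sv2)], atol=1e-9)
        assert np.allclose(res.loadings.T @ res.loadings,
                           np.eye(res.loadings.shape[1]), atol=1e-10)
        assert np.allclose(x @ res.loadings, res.scores, atol=1e-10)

    def test_r_beyond_rank_errors(self):
        x = np.column_stack([np.arange(5.0) - 2.0, 2 * (np.arange(5.0) - 2.0)])
        with pytest.raises(ValueError, match="rank"):
            dapc.pca(x, r=2)


class TestFitDapc:
    def test_axis_count_capped_at_groups_minus_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20, 6))
        labels = np.repeat(["a", "b"], 10)
        model = dapc.fit_dapc(x, labels, n_pca=4, n_da=5)
        assert model.n_da == 1

    def test_separable_clusters_fully_recovered(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0]], dtype=float)
        x = np.vstack([c + rng.standard_normal((15, 3)) for c in centers])
        labels = np.repeat(["a", "b", "c"], 15)
        model = dapc.fit_dapc(x, labels, n_pca=3)
        post = dapc.posterior_memberships(model, x)
        pred = np.array(model.groups)[post.to_numpy().argmax(axis=1)]
        assert np.mean(pred == labels) == 1.0

    def test_duplicating_specimens_leaves_axes_unchanged_up_to_sign(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((30, 5)) + np.repeat([[0] * 5, [2] * 5, [4] * 5],
                                                     10, axis=0)
        labels = np.repeat(["a", "b", "c"], 10)
        m1 = dapc.fit_dapc(x, labels, n_pca=4)
        m2 = dapc.fit_dapc(np.vstack([x, x]), np.concatenate([labels, labels]),
                           n_pca=4)
        a1 = m1.pc_basis @ m1.disc_axes
        a2 = m2.pc_basis @ m2.disc_axes
        for j in range(a1.shape[1]):
            u = a1[:, j] / np.linalg.norm(a1[:, j])
            v = a2[:, j] / np.linalg.norm(a2[:, j])
            assert abs(abs(u @ v) - 1.0) < 1e-6

    def test_tiny_group_named_in_error(self):
        x = np.random.default_rng(6).standard_normal((5, 3))
        with pytest.raises(ValueError, match="lonely"):
            dapc.fit_dapc(x, ["a", "a", "a", "a", "lonely"], n_pca=1)


class TestPosteriorMemberships:
    def test_rows_sum_to_one_and_nonnegative(self, separated_dataset):
        _, _, features, labels = separated_dataset
        model = dapc.fit_dapc(features, labels, n_pca=10)
        post = dapc.posterior_memberships(model, features)
        vals = post.to_numpy()
        assert np.allclose(vals.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(vals >= 0)

    def test_point_at_centroid_dominates(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0.0, 0.0], [10.0, 0.0]])
        x = np.vstack([c + 0.5 * rng.standard_normal((10, 2)) for c in centers])
        labels = np.repeat(["a", "b"], 10)
        model = dapc.fit_dapc(x, labels, n_pca=2, priors="uniform")
        # reconstruct a feature vector that lands exactly on centroid 'a'
        post = dapc.posterior_memberships(model, x[labels == "a"].mean(axis=0))
        assert post.iloc[0]["a"] > 0.99

    def test_equidistant_point_splits_evenly(self):
        x = np.array([[0.0, 1.0], [0.0, -1.0], [4.0, 1.0], [4.0, -1.0]])
        labels = ["a", "a", "b", "b"]
        model = dapc.fit_dapc(x, labels, n_pca=1, priors="uniform")
        mid = np.array([[2.0, 0.0]])
        post = dapc.posterior_memberships(model, mid)
        assert post.iloc[0]["a"] == pytest.approx(0.5, abs=1e-9)

    def test_matches_full_space_gaussian_posterior_oracle(self):
        # independent route: posterior from full-space Gaussian densities
        # with the unbiased pooled within-group covariance must equal the
        # whitened-discriminant-subspace computation
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(8)
        x = rng.standard_normal((40, 5))
        x[:15] += [2, 0, 0, 0, 0]
        x[15:25] += [0, 3, 0, 0, 0]
        labels = np.array(["a"] * 15 + ["b"] * 10 + ["c"] * 15)
        model = dapc.fit_dapc(x, labels, n_pca=5)
        ours = dapc.posterior_memberships(model, x).to_numpy()

        groups = sorted(set(labels))
        pooled = sum(
            (x[labels == g] - x[labels == g].mean(axis=0)).T
            @ (x[labels == g] - x[labels == g].mean(axis=0))
            for g in groups
        ) / (len(x) - len(groups))
        priors = np.array([np.mean(labels == g) for g in groups])
        dens = np.column_stack(
            [
                multivariate_normal.pdf(x, mean=x[labels == g].mean(axis=0),
                                        cov=pooled)
                for g in groups
            ]
        )
        oracle = dens * priors
        oracle /= oracle.sum(axis=1, keepdims=True)
        assert np.allclose(ours, oracle, atol=1e-8)

    def test_predictions_agree_with_sklearn_lda(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((45, 4))
        x[:15] += [2.5, 0, 0, 0]
        x[30:] += [0, 2.5, 0, 0]
        labels = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
        model = dapc.fit_dapc(x, labels, n_pca=4)
        post = dapc.posterior_memberships(model, x)
        ours = np.array(model.groups)[post.to_numpy().argmax(axis=1)]
        theirs = LinearDiscriminantAnalysis(solver="eigen").fit(x, labels).predict(x)
        assert np.mean(ours == theirs) == 1.0

    def test_dimension_mismatch(self, separated_dataset):
        _, _, features, labels = separated_dataset
        model = dapc.fit_dapc(features, labels, n_pca=5)
        with pytest.raises(ValueError, match="dimension"):
            model.transform(np.zeros((1, 3)))


class TestCrossval:
    def test_single_feasible_level_is_chosen(self, separated_dataset):
        _, _, features, labels = separated_dataset
        rep = dapc.crossval_dapc(features, labels, pc_grid=[7], replicates=5, seed=1)
        assert rep.chosen_n_pca == 7

    def test_separated_data_high_success(self, separated_dataset):
        _, _, features, labels = separated_dataset
        rep = dapc.crossval_dapc(features, labels, pc_grid=[5, 10], replicates=30,
                                 seed=2)
        assert rep.mean_success[rep.chosen_n_pca] >= 0.95

    def test_permuted_labels_near_chance(self, separated_dataset):
        _, _, features, labels = separated_dataset
        rng = np.random.default_rng(3)
        shuffled = rng.permutation(labels)
        rep = dapc.crossval_dapc(features, shuffled, pc_grid=[5], replicates=60,
                                 seed=4)
        mean = rep.mean_success[5]
        se = rep.success_sd[5] / np.sqrt(rep.replicates)
        assert abs(mean - 1 / 3) <= 3 * max(se, 0.02)

    def test_same_seed_reproducible(self, separated_dataset):
        _, _, features, labels = separated_dataset
        a = dapc.crossval_dapc(features, labels, pc_grid=[5, 10], replicates=10,
                               seed=9)
        b = dapc.crossval_dapc(features, labels, pc_grid=[5, 10], replicates=10,
                               seed=9)
        assert a.chosen_n_pca == b.chosen_n_pca
        assert a.mean_success == b.mean_success
        assert a.pgmp.equals(b.pgmp)

    def test_infeasible_level_skipped_with_warning(self, separated_dataset):
        _, _, features, labels = separated_dataset
        with pytest.warns(UserWarning, match="infeasible"):
            rep = dapc.crossval_dapc(features, labels, pc_grid=[5, 999],
                                     replicates=3, seed=5)
        assert rep.pc_grid == [5]

    def test_empty_feasible_grid_errors(self, separated_dataset):
        _, _, features, labels = separated_dataset
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="feasible"):
                dapc.crossval_dapc(features, labels, pc_grid=[9999], replicates=3,
                                   seed=6)

    def test_held_out_pgmp_rows_sum_to_one(self, separated_dataset):
        _, _, features, labels = separated_dataset
        rep = dapc.crossval_dapc(features, labels, pc_grid=[5], replicates=20,
                                 seed=7)
        seen = rep.replicate_counts > 0
        sums = rep.pgmp[seen.to_numpy()].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
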