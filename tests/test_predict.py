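import numpy as np
import pytest

import fcga
from fcga.io_formats import GradientSet, ParcellationMap
from fcga.predict import (
    G2P,
    P2G,
    FeatureTable,
    build_feature_table,
    compare_constructions,
    default_lambda_grid,
    nested_fold_indices,
    parcel_average_gradients,
    parcellated_gradients,
    permutation_baseline,
    ridge_cv_predict,
)


def _linear_problem(n_subjects=40, n_features=10, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_subjects, n_features))
    beta = rng.standard_normal(n_features)
    y = x @ beta + noise * rng.standard_normal(n_subjects)
    return x, y


class TestFeatureConstruction:
    def test_constant_gradient_parcel_means(self):
        gs = GradientSet(np.full((8, 2), 3.0), np.array([0.6, 0.4]))
        p = ParcellationMap(np.array([1, 1, 2, 2, 3, 3, 4, 4]))
        np.testing.assert_allclose(parcel_average_gradients(gs, p, 2), 3.0)

    def test_identity_parcellation_is_verbatim(self, small_gradients):
        p = ParcellationMap(np.arange(1, 101))
        feats = parcel_average_gradients(small_gradients, p, 5)
        np.testing.assert_array_equal(
            feats, small_gradients.coefficients[:, :5].ravel()
        )

    def test_parcel_major_gradient_minor_order(self):
        coeffs = np.column_stack([[1.0, 3.0, 5.0, 7.0], [0.0, 2.0, 4.0, 6.0]])
        gs = GradientSet(coeffs, np.array([0.7, 0.3]))
        p = ParcellationMap(np.array([1, 1, 2, 2]))
        feats = parcel_average_gradients(gs, p, 2)
        # parcel 1: gradients (2, 1); parcel 2: gradients (6, 5)
        np.testing.assert_allclose(feats, [2.0, 1.0, 6.0, 5.0])

    def test_parcellated_identity_equals_full(self, small_timeseries):
        n = small_timeseries.n_vertices
        p = ParcellationMap(np.arange(1, n + 1))
        feats = parcellated_gradients(small_timeseries, p, 4)
        full = fcga.full_gradients(small_timeseries, 4, zero_variance="zero")
        np.testing.assert_allclose(feats, full.coefficients.ravel(), atol=1e-12)

    def test_parcellated_deterministic(self, small_timeseries, cortex10):
        p = cortex10.block_parcellation(25)
        a = parcellated_gradients(small_timeseries, p, 5)
        b = parcellated_gradients(small_timeseries, p, 5)
        np.testing.assert_array_equal(a, b)

    def test_constructions_differ_at_coarse_parcellation(self, small_timeseries, cortex10):
        p = cortex10.block_parcellation(25)
        lm = fcga.select_random_vertices(100, 30, seed=1)
        g2p = build_feature_table(
            [small_timeseries], p, G2P, landmark_set=lm, g=5
        )
        p2g = build_feature_table([small_timeseries], p, P2G, g=5)
        assert not np.allclose(g2p.features, p2g.features)

    def test_too_many_gradients_rejected(self, small_gradients):
        p = ParcellationMap(np.arange(1, 101))
        with pytest.raises(ValueError, match="gradients"):
            parcel_average_gradients(small_gradients, p, 6)


class TestNestedCV:
    def test_folds_partition_subjects(self):
        for train, test, _ in nested_fold_indices(47, 10, random_state=3):
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 47
        all_test = np.concatenate(
            [t for _, t, _ in nested_fold_indices(47, 10, random_state=3)]
        )
        np.testing.assert_array_equal(np.sort(all_test), np.arange(47))

    def test_inner_splits_never_touch_test_fold(self):
        # zero-leakage assertion: every inner index is an outer-training one
        for train, test, inner in nested_fold_indices(50, 10, random_state=0):
            train_set = set(train.tolist())
            for itr, ival in inner:
                assert set(itr.tolist()) <= train_set
                assert set(ival.tolist()) <= train_set
                assert not set(ival.tolist()) & set(test.tolist())

    def test_noiseless_linear_target_interpolated(self):
        x, y = _linear_problem(noise=0.0)
        report = ridge_cv_predict(
            x, y, n_repeats=3, lambda_grid=np.array([1e-6, 1e-3]), seed=0
        )
        assert np.all(report.per_repeat_r > 0.99)

    def test_permuted_target_carries_no_signal(self):
        # under a permuted target, cross-validated r sits near zero with the
        # well-known slight negative bias of CV predictions under the null
        # (held-out predictions shrink toward the training-fold mean)
        x, y = _linear_problem(n_subjects=300, seed=2)
        y_perm = np.random.default_rng(5).permutation(y)
        report = ridge_cv_predict(
            x, y_perm, n_repeats=5, lambda_grid=np.geomspace(1e-2, 1e2, 5), seed=1
        )
        assert abs(report.per_repeat_r.mean()) < 0.2
        assert report.per_repeat_r.mean() < 0.05

    def test_same_seed_identical_reports(self):
        x, y = _linear_problem(noise=0.5)
        a = ridge_cv_predict(x, y, n_repeats=2, seed=7)
        b = ridge_cv_predict(x, y, n_repeats=2, seed=7)
        np.testing.assert_array_equal(a.per_repeat_mae, b.per_repeat_mae)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_huge_lambda_predicts_training_mean(self):
        x, y = _linear_problem(noise=0.2, seed=3)
        report = ridge_cv_predict(
            x, y, n_repeats=1, lambda_grid=np.array([1e9]), seed=0
        )
        mean_mae = np.abs(y - y.mean()).mean()
        assert report.per_repeat_mae[0] == pytest.approx(mean_mae, rel=0.15)

    def test_constant_target_rejected(self):
        x, _ = _linear_problem()
        with pytest.raises(ValueError, match="constant"):
            ridge_cv_predict(x, np.ones(40), n_repeats=1, seed=0)

    def test_empty_lambda_grid_rejected(self):
        x, y = _linear_problem()
        with pytest.raises(ValueError, match="empty"):
            ridge_cv_predict(x, y, n_repeats=1, lambda_grid=np.array([]), seed=0)

    def test_too_few_subjects_rejected(self):
        x, y = _linear_problem(n_subjects=20)
        with pytest.raises(ValueError, match="subjects"):
            ridge_cv_predict(x, y, n_folds=10, n_repeats=1, seed=0)

    def test_default_lambda_grid_shape(self):
        x, y = _linear_problem()
        grid = default_lambda_grid(x, y)
        assert grid.shape == (30,)
        assert grid[-1] / grid[0] == pytest.approx(1e3, rel=1e-6)


class TestPermutationBaseline:
    def test_strong_signal_minimum_p(self):
        x, y = _linear_problem(noise=0.01, seed=1)
        report = permutation_baseline(
            x, y, n_perm=25, lambda_grid=np.array([1e-4, 1e-2]), seed=0
        )
        assert report.p_value_r == pytest.approx(1.0 / 26.0)

    def test_no_signal_large_p(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        report = permutation_baseline(
            x, y, n_perm=40, lambda_grid=np.geomspace(1e-2, 1e2, 5), seed=2
        )
        assert report.p_value_r > 0.05

    def test_zero_permutations_rejected(self):
        x, y = _linear_problem()
        with pytest.raises(ValueError):
            permutation_baseline(x, y, n_perm=0, seed=0)


class TestCompareConstructions:
    def test_identical_tables_give_zero_differences(self):
        x, y = _linear_problem(noise=0.3, seed=4)
        ft = FeatureTable(x, G2P, n_parcels=2, g=5)
        a = ridge_cv_predict(ft, y, n_repeats=4, seed=11)
        b = ridge_cv_predict(ft, y, n_repeats=4, seed=11)
        np.testing.assert_array_equal(a.per_repeat_mae, b.per_repeat_mae)

    def test_bonferroni_with_one_comparison_is_raw(self, monkeypatch):
        from scipy.stats import binomtest

        raw = binomtest(9, 10).pvalue
        # with n_comparisons=1 the adjusted p equals the raw sign-test p
        assert min(1.0, raw * 1) == raw

    def test_mismatched_cohort_rejected(self, small_timeseries, cortex10):
        p = cortex10.block_parcellation(25)
        lm = fcga.select_random_vertices(100, 20, seed=0)
        with pytest.raises(ValueError, match="per subject"):
            compare_constructions(
                [small_timeseries], p, np.array([1.0, 2.0]), landmark_set=lm
            )
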