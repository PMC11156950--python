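import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fcga
from fcga.core import (
    AffinityMatrix,
    ConnectivityMatrix,
    cosine_affinity,
    cost_summary,
    fcga_from_dense_fc,
    landmark_connectivity_from_dense_fc,
    pca_gradients,
    pearson_connectivity,
    threshold_rows_top_positive,
)
from fcga.io_formats import ParcellationMap
from fcga.landmarks import LandmarkSet, landmarks_from_parcellation


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
            ([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], -1.0),
            # hand oracle: cov/(sx*sy) = 1 / sqrt(42/9 * 2) = 3/sqrt(84)
            ([1.0, 2.0, 4.0], [1.0, 3.0, 2.0], 3.0 / np.sqrt(84.0)),
        ],
    )
    def test_hand_values(self, x, y, expected):
        cm = pearson_connectivity(np.atleast_2d(x), np.atleast_2d(y))
        assert cm.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises_by_default(self):
        x = np.vstack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_connectivity(x, x)

    def test_zero_variance_policy_zero(self):
        x = np.vstack([np.ones(4), np.arange(4.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = pearson_connectivity(x, x, zero_variance="zero")
        assert cm.values[0, 0] == 0.0 and cm.values[1, 1] == 1.0

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="timepoints"):
            pearson_connectivity(np.ones((2, 2)), np.ones((2, 2)))


class TestThreshold:
    def test_ten_percent_of_ten_keeps_one(self):
        row = np.array([[0.5, 0.2, -0.3, 0.1, 0.9, 0.4, -0.1, 0.05, 0.3, 0.7]])
        out = threshold_rows_top_positive(ConnectivityMatrix(row), 0.10)
        expected = np.zeros((1, 10))
        expected[0, 4] = 0.9
        np.testing.assert_array_equal(out.values, expected)
        assert out.thresholded

    def test_all_negative_row_zeroed_with_warning(self):
        row = np.array([[-0.5, -0.2, -0.9]])
        with pytest.warns(UserWarning, match="no positive"):
            out = threshold_rows_top_positive(ConnectivityMatrix(row))
        np.testing.assert_array_equal(out.values, np.zeros((1, 3)))

    def test_fewer_positives_than_m_keeps_all(self):
        row = np.array([[0.2, 0.1]])
        out = threshold_rows_top_positive(ConnectivityMatrix(row), 0.9)
        np.testing.assert_array_equal(out.values, row)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            threshold_rows_top_positive(ConnectivityMatrix(np.ones((1, 2))), 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 1.0))
    def test_idempotent(self, seed, fraction):
        values = np.random.default_rng(seed).uniform(-1, 1, size=(6, 12))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            once = threshold_rows_top_positive(ConnectivityMatrix(values), fraction)
            twice = threshold_rows_top_positive(once, fraction)
        np.testing.assert_array_equal(once.values, twice.values)


class TestCosineAffinity:
    def _thr(self, values):
        return ConnectivityMatrix(np.asarray(values, float), thresholded=True)

    def test_identical_rows_give_one(self):
        a = self._thr([[0.5, 0.0, 0.5]])
        w = cosine_affinity(a, a)
        assert w.values[0, 0] == pytest.approx(1.0)

    def test_half_overlap_hand_value(self):
        a = self._thr([[1.0, 0.0, 1.0]])
        b = self._thr([[1.0, 1.0, 0.0]])
        assert cosine_affinity(a, b).values[0, 0] == pytest.approx(0.5)

    def test_disjoint_support_gives_zero(self):
        a = self._thr([[1.0, 0.0, 0.0]])
        b = self._thr([[0.0, 1.0, 1.0]])
        assert cosine_affinity(a, b).values[0, 0] == 0.0

    def test_zero_row_policy(self):
        a = self._thr([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            w = cosine_affinity(a, a)
        assert w.values[0, 0] == 0.0 and w.values[1, 1] == 1.0
        with pytest.raises(ValueError):
            cosine_affinity(a, a, zero_rows="raise")

    def test_requires_thresholded(self):
        cm = ConnectivityMatrix(np.ones((2, 2)))
        with pytest.raises(ValueError, match="thresholded"):
            cosine_affinity(cm, cm)

    def test_self_affinity_symmetric_unit_diagonal(self, rng):
        values = rng.uniform(0, 1, size=(8, 8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = threshold_rows_top_positive(ConnectivityMatrix(values), 0.3)
            w = cosine_affinity(thr, thr)
        np.testing.assert_allclose(w.values, w.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(w.values), 1.0, atol=1e-12)


class TestPCA:
    def test_single_varying_column_explains_everything(self):
        w = AffinityMatrix(np.column_stack([np.ones(6), np.arange(6.0), np.ones(6)]))
        gs = pca_gradients(w, 1)
        assert gs.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        # independent oracle: eigenvectors of the centered covariance matrix
        values = rng.standard_normal((6, 4))
        gs = pca_gradients(AffinityMatrix(values), 3)
        centered = values - values.mean(axis=0)
        cov = centered.T @ centered
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        scores = centered @ evecs[:, :3]
        # align the oracle's arbitrary signs to the library's convention
        for c in range(3):
            if np.dot(scores[:, c], gs.coefficients[:, c]) < 0:
                scores[:, c] *= -1
        np.testing.assert_allclose(gs.coefficients, scores, atol=1e-10)
        np.testing.assert_allclose(
            gs.explained_variance_ratio, evals[:3] / evals.sum(), atol=1e-12
        )

    def test_output_satisfies_pca_contract(self, small_gradients):
        small_gradients.validate_pca_contract()

    def test_rank_excess_reports_achievable_rank(self):
        w = AffinityMatrix(np.outer(np.arange(5.0), np.ones(4)))
        with pytest.raises(ValueError, match="rank"):
            pca_gradients(w, 3)

    def test_deterministic_sign_convention(self, rng):
        values = rng.standard_normal((10, 5))
        a = pca_gradients(AffinityMatrix(values), 4)
        b = pca_gradients(AffinityMatrix(values.copy()), 4)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestPipeline:
    def test_identity_parcellation_equals_full(self, small_timeseries):
        n = small_timeseries.n_vertices
        full = fcga.full_gradients(small_timeseries, 5, zero_variance="zero")
        lm = landmarks_from_parcellation(ParcellationMap(np.arange(1, n + 1)))
        approx = fcga.fcga(small_timeseries, lm, 5, zero_variance="zero")
        np.testing.assert_array_equal(full.coefficients, approx.coefficients)
        np.testing.assert_array_equal(
            full.explained_variance_ratio, approx.explained_variance_ratio
        )

    def test_deterministic(self, small_timeseries):
        lm = fcga.select_random_vertices(small_timeseries.n_vertices, 20, seed=4)
        a = fcga.fcga(small_timeseries, lm, 5, zero_variance="zero")
        b = fcga.fcga(small_timeseries, lm, 5, zero_variance="zero")
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_provenance_recorded(self, small_timeseries):
        lm = fcga.select_random_vertices(small_timeseries.n_vertices, 20, seed=4)
        gs = fcga.fcga(small_timeseries, lm, 5, zero_variance="zero")
        assert gs.provenance["k"] == 20
        assert gs.provenance["threshold_fraction"] == 0.10
        assert gs.provenance["seed"] == 4

    def test_memory_guard(self, small_timeseries):
        with pytest.raises(ValueError, match="fcga"):
            fcga.full_gradients(small_timeseries, 5, max_vertices=50)

    def test_default_depth_and_fraction(self):
        import inspect

        sig = inspect.signature(fcga.fcga)
        assert sig.parameters["n_components"].default == 25
        assert sig.parameters["fraction"].default == 0.10


class TestDenseFCVariant:
    def test_parcel_column_means_on_printed_toy(self):
        fc = ConnectivityMatrix(np.array([
            [1.0, 0.8, 0.2, 0.4],
            [0.8, 1.0, 0.6, 0.0],
            [0.2, 0.6, 1.0, 0.5],
            [0.4, 0.0, 0.5, 1.0],
        ]))
        lm = landmarks_from_parcellation(ParcellationMap(np.array([1, 1, 2, 2])))
        out = landmark_connectivity_from_dense_fc(fc, lm)
        expected = np.array([
            [0.9, 0.3], [0.9, 0.3], [0.4, 0.75], [0.2, 0.75],
        ])
        np.testing.assert_allclose(out.values, expected)

    def test_identity_parcellation_unchanged(self):
        values = np.random.default_rng(0).uniform(-1, 1, (5, 5))
        fc = ConnectivityMatrix(values)
        lm = landmarks_from_parcellation(ParcellationMap(np.arange(1, 6)))
        out = landmark_connectivity_from_dense_fc(fc, lm)
        np.testing.assert_allclose(out.values, values)

    def test_vertex_landmarks_select_columns(self):
        values = np.random.default_rng(1).uniform(-1, 1, (6, 6))
        fc = ConnectivityMatrix(values)
        lm = LandmarkSet("random_vertices", 2, vertex_indices=np.array([0, 3]))
        out = landmark_connectivity_from_dense_fc(fc, lm)
        np.testing.assert_array_equal(out.values, values[:, [0, 3]])

    def test_dense_fc_pipeline_matches_timeseries_pipeline(self, small_timeseries):
        # the dense-FC entry point with vertex landmarks must reproduce the
        # time-series pipeline when fed the full correlation matrix
        lm = fcga.select_random_vertices(small_timeseries.n_vertices, 30, seed=2)
        direct = fcga.fcga(small_timeseries, lm, 4, zero_variance="zero")
        fc = pearson_connectivity(
            small_timeseries.values, small_timeseries.values, zero_variance="zero"
        )
        via_fc = fcga_from_dense_fc(fc, lm, 4)
        np.testing.assert_allclose(direct.coefficients, via_fc.coefficients, atol=1e-12)


def test_cost_summary_ratio():
    out = cost_summary(2000, 200)
    assert out["affinity_entries"] == 2000 * 200
    assert out["full_entries"] == 2000 * 2000
    assert out["ratio"] == pytest.approx(0.1)
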