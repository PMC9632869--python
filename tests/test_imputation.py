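import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskpol.imputation import (
    MetricParams,
    ObservationMatrix,
    default_metric_params,
    drop_high_missing,
    knn_impute,
    mean_impute,
    orthonormal_embedding,
    pair_dissimilarity,
    rsse,
    scaling_identity_ratio,
    tree_metric,
    triangle_threshold_search,
    triangle_violation_exists,
)

NAN = np.nan


class TestObservationMatrix:
    def test_rejects_fully_missing_feature(self):
        with pytest.raises(ValueError, match="entirely missing"):
            ObservationMatrix(np.array([[1.0, NAN], [2.0, NAN]]))

    def test_csv_roundtrip(self, tmp_path):
        m = ObservationMatrix(np.array([[1.0, NAN], [NAN, 2.0]]), ["a", "b"])
        p = tmp_path / "m.csv"
        m.to_csv(p)
        back = ObservationMatrix.from_csv(p)
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(m.values))
        assert back.feature_names == ["a", "b"]
        assert back.values[0, 0] == 1.0

    def test_drop_high_missing(self):
        vals = np.ones((10, 2))
        vals[:9, 1] = NAN
        m = ObservationMatrix(vals)
        kept, dropped = drop_high_missing(m, threshold=0.5)
        assert dropped == ["f1"]
        assert kept.n_features == 1


class TestMetricParams:
    def test_default_scale_twice_variance(self):
        m = ObservationMatrix(np.array([[0.0, 1.0], [2.0, 2.0]]))
        p = default_metric_params(m)
        # population variance of {0, 2} is 1 -> scale 2
        assert p.scales[0] == pytest.approx(2.0)
        assert p.penalty == 1.0

    def test_constant_feature_named_in_error(self):
        m = ObservationMatrix(np.array([[0.0, 5.0], [1.0, 5.0]]), ["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            default_metric_params(m)

    def test_single_observed_value_rejected(self):
        m = ObservationMatrix(np.array([[0.0, 5.0], [1.0, NAN]]))
        with pytest.raises(ValueError, match="fewer than 2"):
            default_metric_params(m)

    def test_penalty_range_enforced(self):
        with pytest.raises(ValueError):
            MetricParams(scales=np.ones(1), penalty=0.1)
        with pytest.raises(ValueError):
            MetricParams(scales=np.array([0.0]), penalty=1.0)


class TestDissimilarity:
    def test_identical_fully_observed_zero(self):
        p = MetricParams(scales=np.ones(3))
        x = np.array([1.0, 2.0, 3.0])
        assert pair_dissimilarity(x, x, p) == 0.0

    def test_missing_coordinate_contributes_penalty(self):
        p = MetricParams(scales=np.ones(1), penalty=1.0)
        assert pair_dissimilarity(np.array([NAN]), np.array([0.0]), p) == 1.0

    def test_observed_term_value(self):
        p = MetricParams(scales=np.array([2.0]))
        d = pair_dissimilarity(np.array([0.0]), np.array([1.0]), p)
        assert d == pytest.approx(1.0 / 3.0)

    def test_bounded_by_n_and_terms_below_one(self):
        rng = np.random.default_rng(0)
        p = MetricParams(scales=np.full(5, 0.5))
        for _ in range(50):
            x, y = rng.normal(size=5) * 100, rng.normal(size=5) * 100
            d = pair_dissimilarity(x, y, p)
            assert 0 <= d < 5.0

    def test_tree_metric_values(self):
        p1 = MetricParams(scales=np.ones(1), penalty=0.25)
        assert tree_metric(np.array([NAN]), np.array([3.0]), p1) == pytest.approx(0.5)
        # f-values (1/3, 1): x=(0, nan), y=(1, 0), scales (2, 1), a = 1
        p2 = MetricParams(scales=np.array([2.0, 1.0]), penalty=1.0)
        d = tree_metric(np.array([0.0, NAN]), np.array([1.0, 0.0]), p2)
        assert d == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_dimension_mismatch(self):
        p = MetricParams(scales=np.ones(2))
        with pytest.raises(ValueError):
            pair_dissimilarity(np.ones(3), np.ones(3), p)

    @given(st.integers(0, 5000), st.sampled_from([0.25, 0.5, 1.0]))
    @settings(max_examples=150, deadline=None)
    def test_tree_metric_symmetry_and_triangle(self, seed, penalty):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        p = MetricParams(scales=rng.uniform(0.1, 3.0, n), penalty=penalty)
        pts = rng.normal(size=(3, n)) * rng.choice([0.1, 1, 10])
        miss = rng.random((3, n)) < 0.4
        pts[miss] = NAN
        x, y, z = pts
        assert tree_metric(x, y, p) == pytest.approx(tree_metric(y, x, p))
        assert tree_metric(x, z, p) <= tree_metric(x, y, p) + tree_metric(y, z, p) + 1e-12


class TestTriangleThreshold:
    def test_violation_below_quarter(self):
        assert triangle_violation_exists(0.1, n_random=100, seed=0)

    def test_no_violation_at_one(self):
        assert not triangle_violation_exists(1.0, n_random=100_000, seed=0)

    def test_no_violation_at_quarter(self):
        assert not triangle_violation_exists(0.25, n_random=100_000, seed=0)

    def test_threshold_search_returns_quarter(self):
        thr, table = triangle_threshold_search(
            [0.1, 0.2, 0.25, 0.5, 1.0], n_random=20_000, seed=0
        )
        assert thr == 0.25
        assert table.loc[table["penalty"] < 0.25, "violated"].all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            triangle_threshold_search([], n_random=10)


class TestImputers:
    def test_mean_impute_values(self):
        m = ObservationMatrix(np.array([[1.0, 0.0], [3.0, 1.0], [NAN, 2.0]]))
        out = mean_impute(m)
        assert out.values[2, 0] == pytest.approx(2.0)
        assert out.missing_fraction == 0.0

    def test_mean_impute_no_missing_unchanged(self):
        m = ObservationMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_array_equal(mean_impute(m).values, m.values)

    def test_mean_impute_fully_missing_row(self):
        m = ObservationMatrix(np.array([[1.0, 10.0], [3.0, 30.0], [NAN, NAN]]))
        out = mean_impute(m)
        np.testing.assert_allclose(out.values[2], [2.0, 20.0])

    def test_knn_no_missing_identity(self):
        m = ObservationMatrix(np.array([[1.0, 2.0], [3.0, 4.0], [0.0, 1.0]]))
        np.testing.assert_array_equal(knn_impute(m, k=1).values, m.values)

    def test_knn_one_nn_fill(self):
        # row 0 misses f1; by f0 its nearest observer of f1 is row 1
        vals = np.array([[0.0, NAN], [0.1, 5.0], [10.0, 9.0]])
        m = ObservationMatrix(vals)
        out = knn_impute(m, k=1)
        assert out.values[0, 1] == pytest.approx(5.0)
        # observed entries untouched
        assert out.values[1, 1] == 5.0 and out.values[2, 0] == 10.0

    def test_knn_identical_rows(self):
        vals = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, NAN]])
        m = ObservationMatrix(vals)
        params = MetricParams(scales=np.ones(2))
        out = knn_impute(m, k=2, params=params)
        assert out.values[2, 1] == pytest.approx(2.0)

    def test_knn_k_too_large(self):
        m = ObservationMatrix(np.array([[1.0], [2.0], [NAN]]))
        with pytest.raises(ValueError, match="exceeds"):
            knn_impute(m, k=3, params=MetricParams(scales=np.ones(1)))

    def test_knn_fills_everything(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 5))
        mask = rng.random(vals.shape) < 0.3
        vals[mask] = NAN
        out = knn_impute(ObservationMatrix(vals), k=5)
        assert out.missing_fraction == 0.0
        # observed entries preserved
        obs = ~mask
        np.testing.assert_array_equal(out.values[obs], np.where(mask, 0, vals)[obs])


class TestRSSE:
    def test_perfect_zero(self):
        x = np.ones((2, 2))
        assert rsse(x, x, np.zeros((2, 2), bool)) == 0.0

    def test_single_error(self):
        truth = np.zeros((1, 1))
        comp = np.full((1, 1), 3.0)
        assert rsse(comp, truth, np.ones((1, 1), bool)) == 3.0

    def test_pythagorean(self):
        truth = np.zeros((1, 2))
        comp = np.array([[3.0, 4.0]])
        assert rsse(comp, truth, np.ones((1, 2), bool)) == pytest.approx(5.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rsse(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2), bool))


class TestBenchmarks:
    def test_orthonormal_embedding(self):
        rng = np.random.default_rng(0)
        Q = orthonormal_embedding(100, 3, rng)
        np.testing.assert_allclose(Q.T @ Q, np.eye(3), atol=1e-10)

    def test_scaling_identity(self):
        assert scaling_identity_ratio(200_000, seed=0) == pytest.approx(2.0, rel=0.02)
        assert scaling_identity_ratio(200_000, seed=0, dist="exponential") == pytest.approx(
            2.0, rel=0.05
        )

    def test_swiss_roll_masked_fraction_and_claim(self):
        # redundant higher-dimensional embeddings (the construction's premise)
        from riskpol.imputation import swiss_roll_benchmark

        table = swiss_roll_benchmark(600, dims=(6, 12), missing_frac=0.7, seed=0)
        assert (table.loc["knn"] < table.loc["mean"]).all()

    def test_swiss_roll_invalid_fraction(self):
        from riskpol.imputation import swiss_roll_benchmark

        with pytest.raises(ValueError):
            swiss_roll_benchmark(100, dims=(5,), missing_frac=1.2)
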