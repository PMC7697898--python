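import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polarsa import io_qc, polar_cluster as pc
from conftest import brute_force_inertia, hourly_frame


def features_from_points(points: np.ndarray) -> io_qc.PolarFeatures:
    """Wrap an (n, 3) array directly as standardized features (the
    clustering itself is agnostic to how coordinates were produced)."""
    idx = pd.date_range("2018-01-01", periods=len(points), freq="h")
    data = pd.DataFrame(points, columns=["x", "y", "c"], index=idx)
    return io_qc.PolarFeatures(
        data=data, pollutant="pm10", radial_variable="wind_speed",
        n_dropped=0, standardized=True,
        center=pd.Series(0.0, index=["x", "y", "c"]),
        scale=pd.Series(1.0, index=["x", "y", "c"]),
    )


class TestKMeans:
    def test_k1_inertia_is_total_scatter_about_grand_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        sol = pc.kmeans_cluster(features_from_points(X), k=1, seed=0)
        expected = ((X - X.mean(axis=0)) ** 2).sum()
        assert sol.inertia == pytest.approx(expected, rel=1e-12)
        assert (sol.labels == 1).all()

    def test_k_equals_n_distinct_points_gives_zero_inertia(self):
        X = np.arange(18, dtype=float).reshape(6, 3)
        sol = pc.kmeans_cluster(features_from_points(X), k=6, seed=0)
        assert sol.inertia == pytest.approx(0.0, abs=1e-12)

    def test_two_triplet_fixture_matches_brute_force_partition(self):
        X = np.array(
            [[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0],
             [5, 5, 5], [5.1, 5, 5], [5, 5.1, 5]],
            dtype=float,
        )
        sol = pc.kmeans_cluster(features_from_points(X), k=2, n_restarts=20, seed=0)
        labels = sol.labels.to_numpy()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert sol.inertia == pytest.approx(brute_force_inertia(X, 2), rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(*[st.floats(-5, 5, allow_nan=False) for _ in range(3)]),
            min_size=4, max_size=8,
        ),
        k=st.integers(2, 3),
    )
    def test_restarted_lloyd_attains_exhaustive_optimum(self, data, k):
        X = np.array(data, dtype=float)
        sol = pc.kmeans_cluster(features_from_points(X), k=k, n_restarts=20, seed=1)
        assert sol.inertia <= brute_force_inertia(X, k) * (1 + 1e-9) + 1e-12

    def test_determinism_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        a = pc.kmeans_cluster(features_from_points(X), k=4, seed=9)
        b = pc.kmeans_cluster(features_from_points(X), k=4, seed=9)
        assert a.labels.equals(b.labels) and a.inertia == b.inertia

    def test_labels_ordered_by_decreasing_mean_concentration(self):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [rng.normal([0, 0, m], 0.1, (30, 3)) for m in (1.0, 5.0, 9.0)]
        )
        sol = pc.kmeans_cluster(features_from_points(X), k=3, seed=0)
        means = [X[sol.labels.to_numpy() == cl, 2].mean() for cl in (1, 2, 3)]
        assert means[0] > means[1] > means[2]

    def test_k_larger_than_n_rejected(self):
        X = np.zeros((3, 3))
        with pytest.raises(ValueError, match="exceeds"):
            pc.kmeans_cluster(features_from_points(X), k=5)

    def test_unstandardized_features_rejected(self):
        feats = io_qc.to_polar_features(hourly_frame(20), "pm10")
        with pytest.raises(ValueError, match="standardized"):
            pc.kmeans_cluster(feats, k=2)

    def test_matches_sklearn_reference_inertia(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(m, 0.5, (60, 3)) for m in (0.0, 3.0, 6.0)])
        sol = pc.kmeans_cluster(features_from_points(X), k=3, n_restarts=20, seed=0)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert sol.inertia <= ref.inertia_ * (1 + 1e-6)


class TestSweep:
    def test_single_k_range(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        res = pc.sweep_k(features_from_points(X), 1, 1)
        assert list(res.solutions) == [1]

    def test_inertia_nonincreasing_across_k(self):
        X = np.random.default_rng(1).normal(size=(300, 3))
        res = pc.sweep_k(features_from_points(X), 1, 8, n_restarts=5)
        inertias = [res.inertia[k] for k in range(1, 9)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_two_blob_stability_beats_random_relabeling(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (80, 3)), rng.normal(4, 0.3, (80, 3))])
        res = pc.sweep_k(features_from_points(X), 2, 3, n_restarts=10)
        observed = res.stability[(2, 3)]
        from sklearn.metrics import adjusted_rand_score

        base = res.solutions[2].labels.to_numpy()
        random_scores = [
            adjusted_rand_score(base, rng.permutation(res.solutions[3].labels.to_numpy()))
            for _ in range(50)
        ]
        assert observed >= np.mean(random_scores)


class TestCentralCluster:
    def test_ring_cluster_enclosing_origin_ranks_first(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 2 * np.pi, 160)
        ring = np.column_stack([np.sin(theta), np.cos(theta), np.full(160, 8.0)])
        sector_pts = np.column_stack(
            [rng.normal(6, 0.2, 40), rng.normal(6, 0.2, 40), np.full(40, 2.0)]
        )
        X = np.vstack([ring, sector_pts])
        feats = features_from_points(X)
        sol = pc.kmeans_cluster(feats, k=2, seed=0)
        geo = pc.central_cluster_candidates(sol, feats)
        ring_cluster = sol.labels.iloc[0]
        assert geo.loc[ring_cluster, "rank"] == 1
        assert geo.loc[ring_cluster, "hull_contains_origin"]
        assert geo.loc[ring_cluster, "sector_coverage"] == 1.0

    def test_single_sector_cluster_low_coverage_no_origin(self):
        rng = np.random.default_rng(1)
        near = np.column_stack(
            [rng.normal(0.1, 0.02, 50), rng.normal(0.6, 0.02, 50), np.full(50, 5.0)]
        )
        far = np.column_stack(
            [rng.normal(8, 0.2, 50), rng.normal(8, 0.2, 50), np.ones(50)]
        )
        feats = features_from_points(np.vstack([near, far]))
        sol = pc.kmeans_cluster(feats, k=2, seed=0)
        near_cluster = sol.labels.iloc[0]
        geo = pc.central_cluster_candidates(sol, feats)
        assert geo.loc[near_cluster, "sector_coverage"] == 1 / 16
        assert not geo.loc[near_cluster, "hull_contains_origin"]

    def test_tiny_cluster_hull_test_flagged(self):
        X = np.array([[0, 1, 9], [0, 1.01, 9], [5, 5, 1], [5, 5.1, 1], [5.1, 5, 1]], float)
        feats = features_from_points(X)
        sol = pc.kmeans_cluster(feats, k=2, seed=0)
        geo = pc.central_cluster_candidates(sol, feats)
        small = sol.labels.value_counts().idxmin()
        assert geo.loc[small, "hull_test_skipped"]


class TestContributionSeries:
    def test_worked_four_hour_example(self):
        df = hourly_frame(4, pm10=[10.0, 20.0, 30.0, 40.0])
        labels = pd.Series([1, 1, 2, 2], index=pd.DatetimeIndex(df["timestamp"]))
        sol = pc.ClusterSolution(
            k=2, labels=labels, centroids=np.zeros((2, 3)), inertia=0.0,
            n_restarts=0, seed=0,
        )
        contrib = pc.contribution_series(df, sol, "pm10")
        agg = pc.aggregate_contributions(contrib, freq="D")
        assert agg.loc[agg.index[0], (1, "mean")] == pytest.approx(7.5)
        assert agg.loc[agg.index[0], (2, "mean")] == pytest.approx(17.5)
        assert df["pm10"].mean() == pytest.approx(25.0)

    def test_single_cluster_series_equals_concentration(self):
        df = hourly_frame(24)
        feats = io_qc.standardize(io_qc.to_polar_features(df, "pm10"))
        sol = pc.kmeans_cluster(feats, k=1, seed=0)
        contrib = pc.contribution_series(df, sol, "pm10")
        np.testing.assert_allclose(contrib[1].to_numpy(), df["pm10"].to_numpy())

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 5))
    def test_additivity_property(self, seed, k):
        rng = np.random.default_rng(seed)
        df = hourly_frame(120, pm10=rng.uniform(1, 100, 120))
        feats = io_qc.standardize(io_qc.to_polar_features(df, "pm10"))
        sol = pc.kmeans_cluster(feats, k=k, n_restarts=3, seed=seed)
        contrib = pc.contribution_series(df, sol, "pm10")
        np.testing.assert_allclose(
            contrib.sum(axis=1).to_numpy(), df["pm10"].to_numpy(), rtol=1e-12
        )

    def test_missing_pollutant_hours_dropped_and_counted(self):
        df = hourly_frame(24)
        feats = io_qc.standardize(io_qc.to_polar_features(df, "pm10"))
        sol = pc.kmeans_cluster(feats, k=2, seed=0)
        df2 = df.copy()
        df2.loc[5, "pm25"] = np.nan
        contrib = pc.contribution_series(df2, sol, "pm25")
        assert len(contrib) == 23
        assert contrib.attrs["dropped_missing_pollutant"] == 1
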