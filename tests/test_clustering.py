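from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from practice_archetypes import clustering
from practice_archetypes.clustering import (
    METROPOLITAN,
    NON_METROPOLITAN,
    StandardisationParams,
    centroid_summary,
    fit_kmeans,
    inertia_curve,
    label_clusters,
    labelled_assignments,
    pca_project,
    select_k_elbow,
    select_k_silhouette,
    standardise,
)
from practice_archetypes.features import FEATURE_ORDER
from practice_archetypes.synthetic_data import sample_feature_level


def brute_force_two_means(X):
    """Exhaustive optimal 2-partition SSE (oracle for k=2 k-means)."""
    n = len(X)
    best = np.inf
    for size in range(1, n // 2 + 1):
        for subset in combinations(range(n), size):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            a, b = X[mask], X[~mask]
            sse = (((a - a.mean(axis=0)) ** 2).sum()
                   + ((b - b.mean(axis=0)) ** 2).sum())
            best = min(best, sse)
    return best


def make_profiles(matrix):
    frame = pd.DataFrame(np.asarray(matrix, dtype=float), columns=FEATURE_ORDER)
    frame.insert(0, "practice_id", [f"P{i}" for i in range(len(frame))])
    return frame


class TestStandardise:
    def test_zero_mean_unit_sd(self, profiles):
        Z, _ = standardise(profiles)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.std(ddof=1, axis=0) - 1).max() < 1e-9

    def test_inverse_round_trip(self, profiles):
        Z, params = standardise(profiles)
        back = params.inverse(Z.to_numpy())
        np.testing.assert_allclose(back, profiles[FEATURE_ORDER].to_numpy(),
                                   rtol=1e-9, atol=1e-6)

    def test_two_point_closed_form(self):
        # two rows: z = +/- 1/sqrt(2) under the sample-SD convention
        rng = np.random.default_rng(1)
        rows = rng.uniform(1, 10, size=(1, 6))
        profiles = make_profiles(np.vstack([rows, rows + 3.0]))
        Z, _ = standardise(profiles)
        np.testing.assert_allclose(np.abs(Z.to_numpy()), 1 / np.sqrt(2), rtol=1e-12)

    def test_constant_column_named(self, profiles):
        frozen = profiles.copy()
        frozen["sd_distance_km"] = 1.0
        with pytest.raises(ValueError, match="sd_distance_km"):
            standardise(frozen)


class TestFitKMeans:
    def test_one_dimensional_two_clusters(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        model = fit_kmeans(X, 2, seed=0)
        assert model.inertia == pytest.approx(1.0)
        groups = {frozenset(model.assignments[model.assignments == c].index)
                  for c in (0, 1)}
        assert groups == {frozenset({0, 1}), frozenset({2, 3})}
        assert sorted(model.centroids_standardised.ravel()) == pytest.approx([0.5, 10.5])

    def test_k_equals_one_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        model = fit_kmeans(X, 1, seed=0)
        np.testing.assert_allclose(model.centroids_standardised[0], X.mean(axis=0))
        assert model.inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2))
        assert fit_kmeans(X, 6, seed=0).inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_above_n_errors(self):
        with pytest.raises(ValueError):
            fit_kmeans(np.zeros((3, 2)), 4, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        a = fit_kmeans(X, 3, seed=9)
        b = fit_kmeans(X, 3, seed=9)
        assert a.inertia == b.inertia
        assert (a.assignments == b.assignments).all()

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 9))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        model = fit_kmeans(X, 2, seed=trial, n_init=50)
        assert model.inertia == pytest.approx(brute_force_two_means(X), rel=1e-9)


class TestKSelection:
    @staticmethod
    def three_blobs(seed=0, spread=0.1):
        rng = np.random.default_rng(seed)
        centres = np.array([[0, 0], [50, 0], [0, 50]], dtype=float)
        return np.vstack([c + rng.normal(scale=spread, size=(12, 2)) for c in centres])

    def test_inertia_curve_monotone(self, feature_cohort):
        feats, _, _ = feature_cohort
        Z, _ = standardise(feats)
        curve = inertia_curve(Z, range(1, 8), seed=0, n_init=10)
        assert (np.diff(curve.to_numpy()) <= 1e-9).all()

    def test_inertia_curve_single_k(self):
        X = self.three_blobs()
        curve = inertia_curve(X, [1], seed=0, n_init=5)
        assert list(curve.index) == [1]

    def test_elbow_on_three_blobs(self):
        X = self.three_blobs()
        curve = inertia_curve(X, range(1, 7), seed=0, n_init=20)
        assert select_k_elbow(curve) == 3

    def test_elbow_linear_curve_tie_break(self):
        inertias = {k: 100.0 - 10.0 * k for k in range(1, 6)}
        assert select_k_elbow(inertias) == 2

    def test_elbow_short_curve_errors(self):
        with pytest.raises(ValueError):
            select_k_elbow({1: 3.0, 2: 2.0, 3: 1.0})

    def test_silhouette_on_three_blobs(self):
        rng = np.random.default_rng(1)
        centres = np.array([[0, 0], [40, 0], [0, 40]], dtype=float)
        X = np.vstack([c + rng.normal(scale=0.01, size=(2, 2)) for c in centres])
        assert select_k_silhouette(X, range(2, 5), seed=0, n_init=10) == 3

    def test_silhouette_single_candidate(self):
        X = self.three_blobs()
        assert select_k_silhouette(X, [2], seed=0, n_init=5) == 2


class TestPCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 10)[:, None]
        direction = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        scores, explained = pca_project(t @ direction)
        assert explained[0] == pytest.approx(1.0)
        assert explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_isometry_on_planar_data(self):
        rng = np.random.default_rng(7)
        plane = rng.normal(size=(15, 2))
        basis, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        X = plane @ basis.T
        scores, _ = pca_project(X)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(scores.to_numpy()), pdist(X), rtol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        _, explained = pca_project(X)
        cov = np.cov(X, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(explained, eigvals[:2] / eigvals.sum(), rtol=1e-9)
        assert explained[0] >= explained[1] > 0

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            pca_project(np.zeros((2, 6)))

    def test_beats_random_projections(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 6)) * np.array([5, 3, 1, 1, 0.5, 0.2])
        X = X - X.mean(axis=0)
        scores, _ = pca_project(X)
        pca_var = scores.to_numpy().var(axis=0, ddof=1).sum()
        total = X.var(axis=0, ddof=1).sum()
        for _ in range(20):
            basis, _ = np.linalg.qr(rng.normal(size=(6, 2)))
            rand_var = (X @ basis).var(axis=0, ddof=1).sum()
            assert rand_var <= pca_var + 1e-9
        assert pca_var <= total + 1e-9


def params_with(density_pair, pharmacy_pair):
    """Params whose inverse maps centroid rows onto chosen density/pharmacy values."""
    means = np.zeros(6)
    sds = np.ones(6)
    params = StandardisationParams(tuple(FEATURE_ORDER), means, sds)
    centroids = np.zeros((2, 6))
    centroids[:, FEATURE_ORDER.index("population_density")] = density_pair
    centroids[:, FEATURE_ORDER.index("n_pharmacies")] = pharmacy_pair
    return params, centroids


class TestLabelling:
    @staticmethod
    def model_from(centroids):
        assignments = pd.Series([0, 1], index=["P0", "P1"])
        return clustering.ClusterModel(k=2, assignments=assignments,
                                       centroids_standardised=centroids,
                                       inertia=0.0, seed=0)

    def test_table_density_values(self):
        params, centroids = params_with([5180.0, 1272.0], [212.0, 98.0])
        model = label_clusters(self.model_from(centroids), params)
        assert model.labels == {0: METROPOLITAN, 1: NON_METROPOLITAN}

    def test_labels_follow_density_not_index(self):
        params, centroids = params_with([1272.0, 5180.0], [98.0, 212.0])
        model = label_clusters(self.model_from(centroids), params)
        assert model.labels == {0: NON_METROPOLITAN, 1: METROPOLITAN}

    def test_density_tie_breaks_on_pharmacies(self):
        params, centroids = params_with([1000.0, 1000.0], [212.0, 98.0])
        model = label_clusters(self.model_from(centroids), params)
        assert model.labels[0] == METROPOLITAN

    def test_k_not_two_errors(self):
        model = fit_kmeans(np.random.default_rng(0).normal(size=(9, 6)), 3, seed=0)
        params = StandardisationParams(tuple(FEATURE_ORDER), np.zeros(6), np.ones(6))
        with pytest.raises(ValueError):
            label_clusters(model, params)


class TestCentroidSummary:
    def test_toy_four_practice_fixture(self):
        matrix = np.array([
            [200, 270, 4, 13, 5000, 5600],
            [220, 268, 5, 13, 5400, 5700],
            [100, 246, 15, 20, 1300, 6000],
            [ 90, 245, 14, 19, 1200, 6100],
        ], dtype=float)
        profiles = make_profiles(matrix)
        Z, params = standardise(profiles)
        model = label_clusters(fit_kmeans(Z, 2, seed=0), params)
        out = centroid_summary(model, params, profiles).set_index(["label", "feature"])
        # de-standardised centroid == within-cluster mean; SD == sample SD
        assert out.loc[(METROPOLITAN, "n_pharmacies"), "centroid"] == pytest.approx(210.0)
        assert out.loc[(METROPOLITAN, "n_pharmacies"), "sd"] == pytest.approx(
            np.std([200, 220], ddof=1))
        assert out.loc[(NON_METROPOLITAN, "population_density"), "centroid"] == pytest.approx(1250.0)

    def test_k_equals_n_round_trip(self):
        rng = np.random.default_rng(12)
        profiles = make_profiles(rng.uniform(1, 100, size=(5, 6)))
        Z, params = standardise(profiles)
        model = fit_kmeans(Z, 5, seed=0)
        back = params.inverse(model.centroids_standardised)
        rows = profiles[FEATURE_ORDER].to_numpy()
        for centroid in back:
            assert np.min(np.abs(rows - centroid).sum(axis=1)) < 1e-8

    def test_singleton_cluster_sd_missing(self):
        matrix = np.array([
            [200, 270, 4, 13, 5000, 5600],
            [100, 246, 15, 20, 1300, 6000],
            [ 90, 245, 14, 19, 1200, 6100],
        ], dtype=float)
        profiles = make_profiles(matrix)
        Z, params = standardise(profiles)
        model = label_clusters(fit_kmeans(Z, 2, seed=0), params)
        out = centroid_summary(model, params, profiles)
        met_sd = out[(out.label == METROPOLITAN) & (out.feature == "n_pharmacies")]["sd"]
        assert np.isnan(met_sd.item())


class TestPipelineInvariants:
    def test_row_permutation_invariance(self, feature_cohort):
        feats, _, _ = feature_cohort
        rng = np.random.default_rng(0)
        shuffled = feats.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out = {}
        for name, frame in (("orig", feats), ("shuffled", shuffled)):
            Z, params = standardise(frame)
            model = label_clusters(fit_kmeans(Z, 2, seed=5), params)
            out[name] = labelled_assignments(model).sort_index()
        pd.testing.assert_series_equal(out["orig"], out["shuffled"])

    def test_feature_level_label_recovery(self, feature_cohort):
        feats, truth_labels, _ = feature_cohort
        Z, params = standardise(feats)
        model = label_clusters(fit_kmeans(Z, 2, seed=42), params)
        labels = labelled_assignments(model)
        ari = adjusted_rand_score(truth_labels.reindex(labels.index), labels)
        assert ari >= 0.9

    def test_inertia_recomputable(self, fitted):
        Z, _, model = fitted
        arr = Z.to_numpy()
        assigned = model.centroids_standardised[model.assignments.to_numpy()]
        recomputed = ((arr - assigned) ** 2).sum()
        assert model.inertia == pytest.approx(recomputed, rel=1e-9)
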