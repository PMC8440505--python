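"""Standardisation, k-means fitting, k selection, PCA projection and labelling.

The pipeline standardises the six practice features to z-scores, fits
k-means with multiple restarts, selects k by the elbow (maximum
second-order difference of the inertia curve) corroborated by the mean
silhouette coefficient, and labels the two clusters Metropolitan /
Non-Metropolitan by their de-standardised population-density centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .features import FEATURE_ORDER

logger = logging.getLogger(__name__)

METROPOLITAN = "Metropolitan"
NON_METROPOLITAN = "Non-Metropolitan"

DEFAULT_N_INIT = 50
DEFAULT_K_RANGE = range(1, 11)


@dataclass(frozen=True)
class StandardisationParams:
    """Per-feature means and sample SDs allowing exact inversion."""

    features: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sds + self.means


@dataclass(frozen=True)
class ClusterModel:
    k: int
    assignments: pd.Series  # practice_id -> cluster index
    centroids_standardised: np.ndarray  # k x n_features
    inertia: float
    seed: int
    labels: Mapping[int, str] | None = None


def standardise(profiles: pd.DataFrame) -> tuple[pd.DataFrame, StandardisationParams]:
    """Z-score the six features (sample SD); error on any constant column."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 practices to standardise")
    X = profiles[FEATURE_ORDER].astype(float)
    sds = X.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant feature column(s): {constant}")
    means = X.mean()
    Z = (X - means) / sds
    Z.index = pd.Index(profiles["practice_id"], name="practice_id")
    params = StandardisationParams(
        features=tuple(FEATURE_ORDER),
        means=means.to_numpy(),
        sds=sds.to_numpy(),
    )
    return Z, params


def _as_matrix(X) -> tuple[np.ndarray, pd.Index]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, pd.RangeIndex(len(arr))


def fit_kmeans(X, k: int, seed: int, n_init: int = DEFAULT_N_INIT) -> ClusterModel:
    """Best-of-``n_init`` k-means (k-means++, Lloyd), deterministic given the seed."""
    arr, index = _as_matrix(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(arr):
        raise ValueError(f"k={k} exceeds number of rows {len(arr)}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        algorithm="lloyd",
        random_state=seed,
    ).fit(arr)
    return ClusterModel(
        k=k,
        assignments=pd.Series(km.labels_, index=index, name="cluster_index"),
        centroids_standardised=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
    )


def inertia_curve(X, k_range: Sequence[int] = DEFAULT_K_RANGE, seed: int = 0,
                  n_init: int = DEFAULT_N_INIT) -> pd.Series:
    """Inertia per k; enforced non-increasing (retries once with more restarts)."""
    ks = sorted(k_range)
    inertias = {k: fit_kmeans(X, k, seed, n_init).inertia for k in ks}
    vals = [inertias[k] for k in ks]
    if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
        logger.warning("inertia curve not monotone; retrying with %d restarts", 4 * n_init)
        inertias = {k: fit_kmeans(X, k, seed, 4 * n_init).inertia for k in ks}
        vals = [inertias[k] for k in ks]
        if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
            raise RuntimeError("inertia curve remains non-monotone after retry")
    return pd.Series(inertias, name="inertia").rename_axis("k")


def select_k_elbow(inertias: pd.Series | Mapping[int, float]) -> int:
    """k maximising the second-order difference of the inertia curve.

    Requires inertia at consecutive k starting from 1; ties break toward
    smaller k.
    """
    s = pd.Series(dict(inertias) if not isinstance(inertias, pd.Series) else inertias)
    ks = sorted(int(k) for k in s.index)
    if len(ks) < 4 or ks[0] != 1 or ks != list(range(1, len(ks) + 1)):
        raise ValueError("need inertias for >= 4 consecutive k values starting at 1")
    best_k, best_curv = None, -np.inf
    for k in ks[1:-1]:
        curv = s[k - 1] - 2.0 * s[k] + s[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return int(best_k)


def silhouette_curve(X, k_range: Sequence[int], seed: int = 0,
                     n_init: int = DEFAULT_N_INIT) -> pd.Series:
    """Mean silhouette coefficient (Euclidean) per k, k in [2, n-1]."""
    arr, _ = _as_matrix(X)
    ks = sorted(k_range)
    if any(k < 2 or k > len(arr) - 1 for k in ks):
        raise ValueError("silhouette defined only for 2 <= k <= n-1")
    scores = {}
    for k in ks:
        model = fit_kmeans(arr, k, seed, n_init)
        scores[k] = float(silhouette_score(arr, model.assignments.to_numpy()))
    return pd.Series(scores, name="mean_silhouette").rename_axis("k")


def select_k_silhouette(X, k_range: Sequence[int], seed: int = 0,
                        n_init: int = DEFAULT_N_INIT) -> int:
    """k maximising the mean silhouette coefficient; ties toward smaller k."""
    scores = silhouette_curve(X, k_range, seed, n_init)
    best_k, best = None, -np.inf
    for k in sorted(scores.index):
        if scores[k] > best + 1e-12:
            best_k, best = int(k), scores[k]
    return best_k


def pca_project(X) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal components with deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is
    positive.  Returns (scores indexed like X, explained-variance
    fractions).
    """
    arr, index = _as_matrix(X)
    if len(arr) < 3:
        raise ValueError("PCA projection requires at least 3 rows")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(arr)
    for j in range(2):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] *= -1.0
    frame = pd.DataFrame(scores, columns=["pc1", "pc2"], index=index)
    return frame, pca.explained_variance_ratio_.copy()


def label_clusters(model: ClusterModel, params: StandardisationParams) -> ClusterModel:
    """Label the k=2 clusters by de-standardised population-density centroid.

    Higher density -> Metropolitan; exact ties broken by the larger
    pharmacy-count centroid.
    """
    if model.k != 2:
        raise ValueError(f"labelling defined only for k=2, got k={model.k}")
    centroids = params.inverse(model.centroids_standardised)
    dens = centroids[:, params.features.index("population_density")]
    if dens[0] == dens[1]:
        pharm = centroids[:, params.features.index("n_pharmacies")]
        metro = int(np.argmax(pharm))
    else:
        metro = int(np.argmax(dens))
    labels = {metro: METROPOLITAN, 1 - metro: NON_METROPOLITAN}
    return replace(model, labels=labels)


def labelled_assignments(model: ClusterModel) -> pd.Series:
    """practice_id -> cluster label for a labelled model."""
    if model.labels is None:
        raise ValueError("model has no cluster labels")
    return model.assignments.map(model.labels).rename("label")


def centroid_summary(model: ClusterModel, params: StandardisationParams,
                     profiles: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-cluster, per-feature centroid (original units) and SD.

    The centroid is the de-standardised k-means centroid; the SD is the
    sample SD of the feature among the cluster's member practices.
    Singleton clusters report a missing SD.
    """
    if model.labels is None:
        raise ValueError("model must be labelled first")
    centroids = params.inverse(model.centroids_standardised)
    members = profiles.set_index("practice_id")
    rows = []
    for idx in range(model.k):
        label = model.labels[idx]
        ids = model.assignments[model.assignments == idx].index
        sub = members.loc[ids]
        for j, feature in enumerate(params.features):
            sd = float(sub[feature].std(ddof=1)) if len(sub) > 1 else float("nan")
            rows.append({
                "label": label,
                "feature": feature,
                "centroid": float(centroids[idx, j]),
                "sd": sd,
            })
    return pd.DataFrame(rows)
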