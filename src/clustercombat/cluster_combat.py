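"""Centralized Cluster ComBat.

Instead of estimating one pair of batch-effect parameters per site, sites
(or individual samples) that share an acquisition effect are pooled into C
clusters found by K-means on the raw feature vectors, and the empirical
Bayes machinery estimates G*C cluster-wise parameters instead of G*M.  The
payoff is twofold: each parameter is estimated from more samples, and an
unseen site can be harmonized without retraining by assigning its samples
to the nearest existing centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .model_core import (
    CovariateTable,
    EBEstimates,
    FeatureTable,
    StandardizationModel,
    apply_harmonization,
    empirical_bayes_shrink,
    fit_feature_wise_ols,
    standardize,
)

__all__ = ["ClusterModel", "HarmonizationModel", "fit_cluster_combat", "transform_unseen"]

SCHEMA_VERSION = "1"
_KMEANS_RETRIES = 5


@dataclass
class ClusterModel:
    """A fitted K-means model reduced to its centroids.

    ``space_tag`` records the clustering space: raw sample feature vectors
    for the centralized variant, per-site parameter vectors for the
    distributed one.  Assignment is argmin Euclidean distance with ties
    broken toward the lowest cluster index, so replay is deterministic.
    """

    n_clusters: int
    centroids: np.ndarray       # (C, d)
    space_tag: str              # "sample-features" | "site-parameters"
    seed: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.n_clusters < 1 or self.centroids.shape[0] != self.n_clusters:
            raise ValueError("centroids row count must equal n_clusters")
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Nearest-centroid index per row; np.argmin breaks ties low."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.centroids.shape[1]:
            raise ValueError(
                f"dimension mismatch: centroids have d={self.centroids.shape[1]}, "
                f"points have d={points.shape[1]}"
            )
        d2 = (
            (points**2).sum(axis=1, keepdims=True)
            - 2.0 * points @ self.centroids.T
            + (self.centroids**2).sum(axis=1)
        )
        return np.argmin(d2, axis=1)


@dataclass
class HarmonizationModel:
    """Serializable bundle of everything needed to harmonize new data:
    the standardization fit, the cluster model (if any) and the cluster- or
    site-wise empirical Bayes estimates."""

    standardization: StandardizationModel
    cluster_model: Optional[ClusterModel]
    eb: EBEstimates
    mode: str  # "combat" | "cluster" | "fed-combat" | "fed-cluster"
    covariate_names: list[str]
    feature_names: list[str]
    schema_version: str = SCHEMA_VERSION
    site_cluster_map: dict = field(default_factory=dict)

    @property
    def n_parameter_groups(self) -> int:
        return len(self.eb.group_labels)


def _fit_kmeans(points: np.ndarray, n_clusters: int, seed: int, min_size: int = 2):
    """K-means with k-means++ and 10 restarts; reseed on undersized clusters."""
    for attempt in range(_KMEANS_RETRIES):
        km = KMeans(
            n_clusters=n_clusters,
            n_init=10,
            random_state=seed + attempt,
            algorithm="lloyd",
        ).fit(points)
        cm = ClusterModel(
            n_clusters=n_clusters,
            centroids=km.cluster_centers_,
            space_tag="sample-features",
            seed=seed + attempt,
        )
        assignment = cm.assign(points)
        sizes = np.bincount(assignment, minlength=n_clusters)
        if np.all(sizes >= min_size):
            return cm, assignment
    raise ValueError(
        f"K-means produced a cluster with fewer than {min_size} members "
        f"after {_KMEANS_RETRIES} reseeds (C={n_clusters}, n={points.shape[0]})"
    )


def fit_cluster_combat(
    features: FeatureTable,
    covariates: CovariateTable,
    n_clusters: int,
    seed: int = 0,
    assignment: Optional[np.ndarray] = None,
) -> HarmonizationModel:
    """Fit Cluster ComBat on multi-site training data.

    Steps: (i) K-means with C clusters on the raw (unstandardized) sample
    feature vectors — samples from the same site may land in different
    clusters; (ii) the usual site-wise OLS standardization fit; (iii)
    empirical Bayes with grouping = sample cluster, so each of the C groups
    pools samples across its member sites; the model stores G*C parameter
    pairs.

    ``assignment`` overrides the K-means labels with a caller-supplied
    integer assignment (centroids are then the cluster means); used to force
    site-identity clusters, under which the fit reduces exactly to classic
    ComBat.
    """
    n = features.n_samples
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds sample count {n}")

    if assignment is None:
        cluster_model, labels = _fit_kmeans(features.values, n_clusters, seed)
    else:
        labels = np.asarray(assignment, dtype=int)
        if labels.shape[0] != n:
            raise ValueError("assignment length must match sample count")
        if set(np.unique(labels)) - set(range(n_clusters)):
            raise ValueError("assignment labels must be in 0..C-1")
        centroids = np.vstack(
            [features.values[labels == c].mean(axis=0) for c in range(n_clusters)]
        )
        cluster_model = ClusterModel(
            n_clusters=n_clusters,
            centroids=centroids,
            space_tag="sample-features",
            seed=seed,
        )
    sizes = np.bincount(labels, minlength=n_clusters)
    if np.any(sizes < 2):
        raise ValueError(f"cluster occupancy below 2: sizes={sizes.tolist()}")

    std_model = fit_feature_wise_ols(features, covariates)
    z = standardize(features, covariates, std_model)
    eb = empirical_bayes_shrink(z, labels)
    # reorder EB groups to plain 0..C-1 so cluster index == row index
    order = np.argsort([int(lab) for lab in eb.group_labels])
    eb = EBEstimates(
        gamma_star=eb.gamma_star[order],
        delta_star_sq=eb.delta_star_sq[order],
        group_labels=[int(eb.group_labels[i]) for i in order],
        iterations=eb.iterations,
        converged=eb.converged,
    )
    return HarmonizationModel(
        standardization=std_model,
        cluster_model=cluster_model,
        eb=eb,
        mode="cluster",
        covariate_names=list(covariates.covariate_names),
        feature_names=list(features.feature_names),
    )


def transform_unseen(
    features: FeatureTable,
    covariates: CovariateTable,
    model: HarmonizationModel,
) -> FeatureTable:
    """Harmonize data from sites never seen in training, with no refitting.

    Each new sample is assigned to the nearest centroid of its raw feature
    vector; the trained alpha/beta/sigma standardize it and the assigned
    cluster's (gamma*, delta*) harmonize it.
    """
    if model.mode not in ("cluster",):
        raise ValueError(
            "retraining-free transform requires a model fit in cluster mode; "
            f"this model is in {model.mode!r} mode"
        )
    if features.n_features != model.standardization.n_features:
        raise ValueError(
            f"feature count mismatch: model has G={model.standardization.n_features}, "
            f"data has G={features.n_features}"
        )
    if list(covariates.covariate_names) != list(model.covariate_names):
        raise ValueError(
            f"covariate schema mismatch: model expects {model.covariate_names}, "
            f"got {list(covariates.covariate_names)}"
        )
    labels = model.cluster_model.assign(features.values)
    z = standardize(features, covariates, model.standardization)
    return apply_harmonization(z, covariates, model.standardization, model.eb, labels)
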