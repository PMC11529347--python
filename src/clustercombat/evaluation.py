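"""Metrics and simulation benchmarks for harmonization quality.

Three complementary views of a harmonization method:

* reconstruction — RMSE between harmonized features and the noiseless
  generator signal alpha + X beta (simulation only, where truth is known);
* downstream utility — accuracy (or MAE) of a linear model trained on
  harmonized training sites and evaluated on harmonized held-out sites;
* effect removal — a "probe" classifier trying to predict the site or
  cluster label from the features; accuracy near chance after harmonization
  means the batch signal is gone.

``run_benchmark`` wires these into the standard protocol: per seed, draw a
preset dataset, hold out 30% of sites, harmonize with each method and
report mean and variance over seeds.  Methods that cannot generalize to
unseen sites (classic and distributed ComBat) are refit on the pooled
train+test sites — the retraining they would need in practice — while the
downstream predictor still only ever trains on training-site rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression

from . import cluster_combat, distributed, model_core, synthetic_data
from .model_core import CovariateTable, FeatureTable
from .synthetic_data import SyntheticDataset, preset_config, subset

__all__ = [
    "BenchmarkResult",
    "rmse_reconstruction",
    "downstream_metric",
    "probe_accuracy",
    "count_significant_features",
    "harmonize_with_method",
    "run_benchmark",
    "METHODS",
]

METHODS = ("none", "combat", "cluster", "fed-combat", "fed-cluster")


@dataclass
class BenchmarkResult:
    method: str
    config: str
    metric: str
    mean: float
    variance: float
    n_seeds: int


def rmse_reconstruction(harmonized, ground_truth: np.ndarray) -> float:
    """Root mean squared elementwise error against the noiseless signal."""
    values = harmonized.values if isinstance(harmonized, FeatureTable) else np.asarray(harmonized)
    truth = np.asarray(ground_truth, dtype=float)
    if values.shape != truth.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean((values - truth) ** 2)))


def downstream_metric(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    test_features: np.ndarray,
    test_targets: np.ndarray,
    task: str = "classify",
) -> float:
    """Linear downstream model: accuracy for ``classify`` (L2-regularized
    logistic regression, C=1), MAE for ``regress`` (ordinary least squares)."""
    if train_features.shape[0] != len(train_targets):
        raise ValueError("train rows and targets misaligned")
    if task == "classify":
        if len(np.unique(train_targets)) < 2:
            raise ValueError("training labels contain a single class")
        clf = LogisticRegression(max_iter=2000)
        clf.fit(train_features, train_targets)
        return float(np.mean(clf.predict(test_features) == test_targets))
    if task == "regress":
        reg = LinearRegression().fit(train_features, train_targets)
        return float(np.mean(np.abs(reg.predict(test_features) - test_targets)))
    raise ValueError(f"unknown task {task!r}")


def probe_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_splits: int = 100,
    test_fraction: float = 0.3,
) -> float:
    """How well a multinomial logistic regression predicts the site/cluster
    label: mean test accuracy over random 70/30 sample-level splits."""
    X = np.asarray(features.values if isinstance(features, FeatureTable) else features)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 label classes")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_test = max(1, int(round(test_fraction * n)))
    accs = []
    for _ in range(n_splits):
        order = rng.permutation(n)
        test, train = order[:n_test], order[n_test:]
        if len(np.unique(y[train])) < 2:
            continue
        clf = LogisticRegression(max_iter=2000)
        clf.fit(X[train], y[train])
        accs.append(np.mean(clf.predict(X[test]) == y[test]))
    return float(np.mean(accs))


def count_significant_features(
    features: np.ndarray,
    target: np.ndarray,
    alpha: float = 0.05,
    n_seeds: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> int:
    """Count features whose per-feature simple-regression p-value, averaged
    over random training splits, falls below ``alpha``.

    The p-value is the two-sided t-test on the slope of a univariate linear
    regression of the target on each feature (equivalent to the test on the
    Pearson correlation), computed on each seed's training rows.
    """
    X = np.asarray(features.values if isinstance(features, FeatureTable) else features, dtype=float)
    y = np.asarray(target, dtype=float)
    n, G = X.shape
    keep = np.std(X, axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance feature(s)", RuntimeWarning
        )
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    pvals = np.zeros(G)
    for _ in range(n_seeds):
        rows = rng.permutation(n)[:n_train]
        Xs, ys = X[rows], y[rows]
        Xc = Xs - Xs.mean(axis=0)
        yc = ys - ys.mean()
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ yc) / (sx * sy)
        r = np.clip(r, -0.999999999, 0.999999999)
        t = r * np.sqrt((n_train - 2) / (1.0 - r**2))
        pvals += 2.0 * stats.t.sf(np.abs(t), df=n_train - 2)
    pvals /= n_seeds
    return int(np.sum((pvals < alpha) & keep))


def _feature_subtable(ds: SyntheticDataset):
    return ds.features, ds.covariates


def harmonize_with_method(
    method: str,
    train: SyntheticDataset,
    test: SyntheticDataset,
    n_clusters: int,
    seed: int,
):
    """Return (harmonized train values, harmonized test values) for one method.

    ``combat`` and ``fed-combat`` are refit on the pooled train+test sites
    (they cannot absorb an unseen site otherwise); ``cluster`` and
    ``fed-cluster`` fit on training sites only and transform the held-out
    sites with no re-estimation.
    """
    if method == "none":
        return train.features.values, test.features.values

    if method in ("combat", "fed-combat"):
        pooled_features = FeatureTable(
            sample_ids=np.concatenate(
                [train.features.sample_ids, test.features.sample_ids]
            ),
            site_ids=np.concatenate([train.features.site_ids, test.features.site_ids]),
            values=np.vstack([train.features.values, test.features.values]),
            feature_names=list(train.features.feature_names),
        )
        pooled_covs = CovariateTable(
            np.vstack([train.covariates.values, test.covariates.values]),
            list(train.covariates.covariate_names),
        )
        n_train = train.features.n_samples
        if method == "combat":
            model = model_core.fit_combat(pooled_features, pooled_covs)
            harm = model_core.transform_sites(pooled_features, pooled_covs, model)
        else:
            _, harm, _ = distributed.run_distributed(
                pooled_features, pooled_covs, n_clusters=0, seed=seed, cluster=False
            )
        return harm.values[:n_train], harm.values[n_train:]

    if method == "cluster":
        model = cluster_combat.fit_cluster_combat(
            train.features, train.covariates, n_clusters=n_clusters, seed=seed
        )
        harm_train = cluster_combat.transform_unseen(
            train.features, train.covariates, model
        )
        harm_test = cluster_combat.transform_unseen(
            test.features, test.covariates, model
        )
        return harm_train.values, harm_test.values

    if method == "fed-cluster":
        model, harm_train, _ = distributed.run_distributed(
            train.features, train.covariates, n_clusters=n_clusters, seed=seed
        )
        pieces = np.empty_like(test.features.values)
        for site in test.features.site_labels():
            rows = test.features.site_ids == site
            ft = FeatureTable(
                sample_ids=test.features.sample_ids[rows],
                site_ids=test.features.site_ids[rows],
                values=test.features.values[rows],
                feature_names=list(test.features.feature_names),
            )
            cv = CovariateTable(
                test.covariates.values[rows], list(test.covariates.covariate_names)
            )
            pieces[rows] = distributed.unseen_site_join(ft, cv, model).values
        return harm_train.values, pieces

    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def run_benchmark(
    presets,
    methods=METHODS,
    n_seeds: int = 30,
    n_clusters: int | None = None,
    train_fraction: float = 0.7,
    max_samples_per_site: int | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """The standard simulation grid: per preset, per seed, generate, hold out
    30% of sites, harmonize with each method, and score reconstruction RMSE
    and downstream label accuracy on the held-out sites.

    ``n_clusters`` defaults to each preset's true cluster count.
    ``max_samples_per_site`` caps every site's rows (small-site stress test).
    Returns a tidy DataFrame of mean/variance per (preset, method, metric).
    """
    rows = []
    for preset in presets:
        cells = {m: {"rmse": [], "accuracy": []} for m in methods}
        for s in range(n_seeds):
            seed = base_seed + s
            ds = synthetic_data.generate_dataset(preset_config(preset, seed=seed))
            if max_samples_per_site is not None:
                mask = _cap_per_site(ds, max_samples_per_site, seed)
                ds = subset(ds, mask)
            C = n_clusters if n_clusters is not None else ds.config.n_clusters
            train_mask, test_mask = synthetic_data.split_by_sites(
                ds, train_fraction, seed=seed
            )
            train, test = subset(ds, train_mask), subset(ds, test_mask)
            for m in methods:
                ht, hx = harmonize_with_method(m, train, test, C, seed)
                cells[m]["rmse"].append(rmse_reconstruction(hx, test.ground_truth))
                cells[m]["accuracy"].append(
                    downstream_metric(ht, train.labels, hx, test.labels, "classify")
                )
        for m in methods:
            for metric, vals in cells[m].items():
                arr = np.asarray(vals)
                rows.append(
                    BenchmarkResult(
                        method=m,
                        config=preset,
                        metric=metric,
                        mean=float(arr.mean()),
                        variance=float(arr.var(ddof=0)) if len(arr) > 1 else 0.0,
                        n_seeds=n_seeds,
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows])


def _cap_per_site(ds: SyntheticDataset, cap: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    mask = np.zeros(ds.features.n_samples, dtype=bool)
    for site in ds.features.site_labels():
        idx = np.flatnonzero(ds.features.site_ids == site)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        mask[idx] = True
    return mask
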