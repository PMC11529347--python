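"""Synthetic multi-site data with cluster-shared batch effects.

The generator draws a hierarchical model in which groups of sites share one
additive/multiplicative batch effect:

    alpha_g   ~ N(0, sd_alpha^2)                    per feature
    beta_pg   ~ N(0, sd_beta^2)                     per covariate and feature
    gamma_cg  ~ N(0, sd_gamma^2)                    per cluster and feature
    delta_cg  ~ Uniform(delta_low, delta_high)      per cluster and feature
    label_j   in {+1, -1}, balanced within each site
    X_jp      ~ N(+0.5, 0.5^2) if label_j = +1 else N(-0.5, 0.5^2)
    y_jg      ~ N(alpha_g + X_j . beta_g + gamma_cg, delta_cg^2 sigma_g^2)

Sites are assigned to clusters in contiguous blocks of ``sites_per_cluster``
(sites 1..k in cluster 0, the next k in cluster 1, ...).  The noiseless,
site-free signal alpha_g + X_j . beta_g is returned as the ground truth that
a perfect harmonization would recover.

Binary class labels are encoded in the covariates through their means
(+0.5 / -0.5 with spread 0.5), so the ground truth is (nearly) linearly
separable and a downstream classifier measures how much biological signal a
harmonization step preserves.

The five bundled presets scale the number of sites, per-site samples and
features together (20/20/20 up to 40/40/50, always 5 sites per cluster and
5 covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import CovariateTable, FeatureTable

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "split_by_sites", "PRESETS", "preset_config"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults give a strong, clearly clustered batch
    effect (between-cluster spread twice the noise scale)."""

    n_sites: int = 20
    samples_per_site: int = 20
    n_features: int = 20
    sites_per_cluster: int = 5
    n_covariates: int = 5
    sd_alpha: float = 1.0
    sd_beta: float = 1.0
    sd_gamma: float = 2.0
    delta_low: float = 0.5
    delta_high: float = 2.0
    sigma_g: float = 1.0
    covariate_mean: float = 0.5
    covariate_sd: float = 0.5
    label_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1 or self.samples_per_site < 1 or self.n_features < 1:
            raise ValueError("n_sites, samples_per_site and n_features must be >= 1")
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be >= 0")
        if self.n_sites % self.sites_per_cluster != 0:
            raise ValueError(
                f"sites_per_cluster={self.sites_per_cluster} must divide "
                f"n_sites={self.n_sites}"
            )
        if min(self.sd_alpha, self.sd_beta, self.sigma_g, self.covariate_sd) <= 0:
            raise ValueError("scale parameters must be positive")
        if self.sd_gamma < 0:
            raise ValueError("sd_gamma must be >= 0")
        if not (0 < self.delta_low <= self.delta_high):
            raise ValueError("need 0 < delta_low <= delta_high")
        if not (0 < self.label_fraction < 1):
            raise ValueError("label_fraction must be in (0, 1)")

    @property
    def n_clusters(self) -> int:
        return self.n_sites // self.sites_per_cluster


# Preset grid: sites / samples-per-site / features scale together.
PRESETS: dict[str, SyntheticConfig] = {
    "data1": SyntheticConfig(n_sites=20, samples_per_site=20, n_features=20),
    "data2": SyntheticConfig(n_sites=25, samples_per_site=25, n_features=25),
    "data3": SyntheticConfig(n_sites=30, samples_per_site=30, n_features=30),
    "data4": SyntheticConfig(n_sites=35, samples_per_site=35, n_features=40),
    "data5": SyntheticConfig(n_sites=40, samples_per_site=40, n_features=50),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)


@dataclass
class SyntheticDataset:
    features: FeatureTable
    covariates: CovariateTable
    labels: np.ndarray                 # +1 / -1 per sample
    true_cluster_of_site: dict         # site label -> cluster index
    true_cluster_of_sample: np.ndarray
    ground_truth: np.ndarray           # (n, G) = alpha + X beta
    true_alpha: np.ndarray             # (G,)
    true_beta: np.ndarray              # (G, P)
    true_gamma: np.ndarray             # (C, G)
    true_delta: np.ndarray             # (C, G)
    config: SyntheticConfig


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; fully determined by ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    M, npersite, G, P = (
        config.n_sites,
        config.samples_per_site,
        config.n_features,
        config.n_covariates,
    )
    C = config.n_clusters
    n = M * npersite

    alpha = rng.normal(0.0, config.sd_alpha, size=G)
    beta = rng.normal(0.0, config.sd_beta, size=(G, P))
    gamma = rng.normal(0.0, config.sd_gamma, size=(C, G))
    delta = rng.uniform(config.delta_low, config.delta_high, size=(C, G))

    cluster_of_site = np.repeat(np.arange(C), config.sites_per_cluster)
    site_per_sample = np.repeat(np.arange(M), npersite)
    cluster_per_sample = cluster_of_site[site_per_sample]

    # balanced labels within each site, order shuffled per site
    n_pos = int(round(config.label_fraction * npersite))
    labels = np.empty(n, dtype=int)
    for i in range(M):
        block = np.concatenate(
            [np.ones(n_pos, dtype=int), -np.ones(npersite - n_pos, dtype=int)]
        )
        rng.shuffle(block)
        labels[i * npersite : (i + 1) * npersite] = block

    mu_x = config.covariate_mean * labels[:, None]
    X = rng.normal(mu_x, config.covariate_sd, size=(n, P))

    ground_truth = alpha + X @ beta.T
    loc = ground_truth + gamma[cluster_per_sample]
    scale = delta[cluster_per_sample] * config.sigma_g
    y = rng.normal(loc, scale)

    site_labels = np.array([f"site{i:02d}" for i in site_per_sample])
    features = FeatureTable(
        sample_ids=np.array([f"s{j:05d}" for j in range(n)]),
        site_ids=site_labels,
        values=y,
        feature_names=[f"f{g}" for g in range(G)],
    )
    covariates = CovariateTable(X, [f"x{p}" for p in range(P)])
    true_cluster_of_site = {
        f"site{i:02d}": int(cluster_of_site[i]) for i in range(M)
    }
    return SyntheticDataset(
        features=features,
        covariates=covariates,
        labels=labels,
        true_cluster_of_site=true_cluster_of_site,
        true_cluster_of_sample=cluster_per_sample,
        ground_truth=ground_truth,
        true_alpha=alpha,
        true_beta=beta,
        true_gamma=gamma,
        true_delta=delta,
        config=config,
    )


def split_by_sites(
    dataset: SyntheticDataset, train_fraction: float = 0.7, seed: int = 0
):
    """Partition whole sites into train/test (the unseen-site protocol).

    floor(train_fraction * M) sites go to training; site order is shuffled
    deterministically by ``seed``.  Returns boolean row masks
    (train_mask, test_mask).
    """
    sites = dataset.features.site_labels()
    m = len(sites)
    if m < 2:
        raise ValueError("need >= 2 sites to split")
    n_train = int(np.floor(train_fraction * m))
    if n_train < 1 or n_train >= m:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty side with M={m}"
        )
    order = np.random.default_rng(seed).permutation(m)
    train_sites = {sites[i] for i in order[:n_train]}
    train_mask = np.array([s in train_sites for s in dataset.features.site_ids])
    return train_mask, ~train_mask


def subset(dataset: SyntheticDataset, mask: np.ndarray) -> SyntheticDataset:
    """Row-subset every aligned field (sites keep their labels)."""
    ft = dataset.features
    features = FeatureTable(
        sample_ids=ft.sample_ids[mask],
        site_ids=ft.site_ids[mask],
        values=ft.values[mask],
        feature_names=list(ft.feature_names),
    )
    covariates = CovariateTable(
        dataset.covariates.values[mask], list(dataset.covariates.covariate_names)
    )
    return SyntheticDataset(
        features=features,
        covariates=covariates,
        labels=dataset.labels[mask],
        true_cluster_of_site=dict(dataset.true_cluster_of_site),
        true_cluster_of_sample=dataset.true_cluster_of_sample[mask],
        ground_truth=dataset.ground_truth[mask],
        true_alpha=dataset.true_alpha,
        true_beta=dataset.true_beta,
        true_gamma=dataset.true_gamma,
        true_delta=dataset.true_delta,
        config=dataset.config,
    )
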