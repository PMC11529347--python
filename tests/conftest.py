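import numpy as np
import pytest

from clustercombat.model_core import CovariateTable, FeatureTable


def make_tables(n_sites=3, per_site=10, n_features=4, n_covariates=2, seed=0,
                gamma_sd=1.0, delta_range=(0.7, 1.5)):
    """Small random multi-site dataset with genuine site effects."""
    rng = np.random.default_rng(seed)
    n = n_sites * per_site
    site_ids = np.repeat([f"S{i}" for i in range(n_sites)], per_site)
    X = rng.normal(0, 1, size=(n, n_covariates))
    alpha = rng.normal(0, 1, size=n_features)
    beta = rng.normal(0, 1, size=(n_features, n_covariates))
    gamma = rng.normal(0, gamma_sd, size=(n_sites, n_features))
    delta = rng.uniform(*delta_range, size=(n_sites, n_features))
    site_idx = np.repeat(np.arange(n_sites), per_site)
    y = alpha + X @ beta.T + gamma[site_idx] + delta[site_idx] * rng.normal(size=(n, n_features))
    features = FeatureTable(
        sample_ids=np.array([f"s{j}" for j in range(n)]),
        site_ids=site_ids,
        values=y,
        feature_names=[f"f{g}" for g in range(n_features)],
    )
    covariates = CovariateTable(X, [f"x{p}" for p in range(n_covariates)])
    return features, covariates


@pytest.fixture
def small_tables():
    return make_tables(seed=42)
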