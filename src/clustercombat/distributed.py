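"""Distributed (federated) Cluster ComBat, simulated in-process.

Sites never ship raw samples.  Round 1: each site fits a local OLS of its
features on its own covariates and sends the intercepts and slopes.  The
server averages them into global (alpha_g, beta_g), derives each site's
additive effect gamma_hat_ig = alpha_hat_ig - alpha_hat_g, and K-means
clusters the M per-site parameter vectors [alpha_i || vec(beta_i) ||
gamma_i].  Round 2: sites send per-feature residual sums of squares against
the global mean structure, from which the server assembles the pooled scale
sigma_g.  Round 3: each site standardizes locally with the global
parameters, runs single-group empirical Bayes, and sends its (gamma*_i,
delta*^2_i); the server averages them within each cluster.  An unseen site
joins later by sending only its local OLS parameters: the trained K-means
assigns the whole site to one cluster, whose stored parameters harmonize it.

All message payloads scale with G (features), never with N (samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .cluster_combat import ClusterModel, HarmonizationModel
from .model_core import (
    CovariateTable,
    EBEstimates,
    FeatureTable,
    StandardizationModel,
    StandardizedMatrix,
    apply_harmonization,
    empirical_bayes_shrink,
    standardize,
)

__all__ = [
    "SiteMessage",
    "LocalEBMessage",
    "ServerBroadcast",
    "RoundLog",
    "site_local_fit",
    "server_initialize",
    "site_local_rss",
    "site_local_eb",
    "server_cluster_aggregate",
    "unseen_site_join",
    "run_distributed",
]

_KMEANS_RETRIES = 5


@dataclass
class SiteMessage:
    """Round-1 site -> server payload: local OLS parameters, no raw samples."""

    site_id: object
    n_samples: int
    alpha_local: np.ndarray     # (G,)
    beta_local: np.ndarray      # (G, P)
    rss_local: Optional[np.ndarray] = None   # (G,), filled in round 2

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"site {self.site_id!r}: need >= 2 samples")
        for arr in (self.alpha_local, self.beta_local):
            if not np.isfinite(arr).all():
                raise ValueError(f"site {self.site_id!r}: non-finite local estimates")

    def payload_arrays(self) -> list[np.ndarray]:
        out = [self.alpha_local, self.beta_local]
        if self.rss_local is not None:
            out.append(self.rss_local)
        return out


@dataclass
class LocalEBMessage:
    """Round-3 site -> server payload: 2*G reals, independent of N_i."""

    site_id: object
    gamma_star: np.ndarray      # (G,)
    delta_star_sq: np.ndarray   # (G,)

    def payload_arrays(self) -> list[np.ndarray]:
        return [self.gamma_star, self.delta_star_sq]


@dataclass
class ServerBroadcast:
    """Server -> sites state: global mean structure, scale, site effects,
    the parameter-space cluster model, and (after the final round) the
    cluster-wise empirical Bayes estimates."""

    alpha_global: np.ndarray                # (G,)
    beta_global: np.ndarray                 # (G, P)
    gamma_hat_site: dict                    # site -> (G,)
    cluster_model: ClusterModel
    cluster_of_site: dict                   # site -> int
    sigma_global: Optional[np.ndarray] = None
    eb_cluster: Optional[EBEstimates] = None


@dataclass
class RoundLog:
    """Record of every message in the simulated exchange."""

    records: list = field(default_factory=list)

    def add(self, round_name: str, direction: str, sender, n_floats: int) -> None:
        self.records.append(
            {
                "round": round_name,
                "direction": direction,
                "party": str(sender),
                "n_floats": int(n_floats),
            }
        )

    def total_floats(self, direction: Optional[str] = None) -> int:
        return sum(
            r["n_floats"]
            for r in self.records
            if direction is None or r["direction"] == direction
        )


def _payload_size(arrays) -> int:
    return int(sum(np.asarray(a).size for a in arrays))


def site_local_fit(
    site_features: FeatureTable, site_covariates: CovariateTable
) -> SiteMessage:
    """Local per-site OLS of each feature on the site's own covariates."""
    n, p = site_features.n_samples, site_covariates.n_covariates
    if n <= p + 1:
        raise ValueError(
            f"site {site_features.site_ids[0]!r}: n={n} too small for P={p} covariates"
        )
    design = np.hstack([np.ones((n, 1)), site_covariates.values])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient local design at site {site_features.site_ids[0]!r}"
        )
    coef, *_ = np.linalg.lstsq(design, site_features.values, rcond=None)
    return SiteMessage(
        site_id=site_features.site_ids[0],
        n_samples=n,
        alpha_local=coef[0],
        beta_local=coef[1:].T,
    )


def _site_parameter_vector(msg: SiteMessage, gamma: np.ndarray) -> np.ndarray:
    return np.concatenate([msg.alpha_local, msg.beta_local.ravel(), gamma])


def server_initialize(
    messages: list[SiteMessage], n_clusters: int, seed: int = 0
) -> ServerBroadcast:
    """Aggregate round-1 messages and cluster sites in parameter space.

    Global alpha_g and beta_g are the *unweighted* means of the local
    estimates; each site's additive effect is then gamma_hat_ig =
    alpha_hat_ig - alpha_hat_g.  K-means runs on the M concatenated vectors
    [alpha_i || vec(beta_i) || gamma_i] with raw Euclidean distance.
    """
    m = len(messages)
    if m < 2:
        raise ValueError("need messages from >= 2 sites")
    if n_clusters > m:
        raise ValueError(f"n_clusters={n_clusters} exceeds site count {m}")
    alpha_global = np.mean([msg.alpha_local for msg in messages], axis=0)
    beta_global = np.mean([msg.beta_local for msg in messages], axis=0)
    gamma_hat_site = {
        msg.site_id: msg.alpha_local - alpha_global for msg in messages
    }
    points = np.vstack(
        [_site_parameter_vector(msg, gamma_hat_site[msg.site_id]) for msg in messages]
    )
    if n_clusters > 1 and np.allclose(points, points[0]):
        raise ValueError(
            "all site parameter vectors identical: clustering with C > 1 is degenerate"
        )
    labels = None
    for attempt in range(_KMEANS_RETRIES):
        km = KMeans(
            n_clusters=n_clusters, n_init=10, random_state=seed + attempt,
            algorithm="lloyd",
        ).fit(points)
        cm = ClusterModel(
            n_clusters=n_clusters,
            centroids=km.cluster_centers_,
            space_tag="site-parameters",
            seed=seed + attempt,
        )
        labels = cm.assign(points)
        if len(np.unique(labels)) == n_clusters:
            cluster_model = cm
            break
    else:
        raise ValueError(
            f"server K-means left a cluster empty after {_KMEANS_RETRIES} reseeds"
        )
    cluster_of_site = {msg.site_id: int(lab) for msg, lab in zip(messages, labels)}
    return ServerBroadcast(
        alpha_global=alpha_global,
        beta_global=beta_global,
        gamma_hat_site=gamma_hat_site,
        cluster_model=cluster_model,
        cluster_of_site=cluster_of_site,
    )


def site_local_rss(
    site_features: FeatureTable,
    site_covariates: CovariateTable,
    broadcast: ServerBroadcast,
) -> np.ndarray:
    """Per-feature residual sum of squares against the global mean structure
    and this site's own additive effect — the site's share of sigma_g^2."""
    site = site_features.site_ids[0]
    gamma = broadcast.gamma_hat_site[site]
    mean = (
        broadcast.alpha_global
        + site_covariates.values @ broadcast.beta_global.T
        + gamma
    )
    return ((site_features.values - mean) ** 2).sum(axis=0)


def server_aggregate_sigma(
    rss_messages: dict, n_of_site: dict
) -> np.ndarray:
    """sigma_g^2 = sum_i RSS_ig / N, assembled from aggregates only."""
    total = sum(rss_messages.values())
    n_total = sum(n_of_site.values())
    sigma_sq = total / n_total
    if np.any(sigma_sq <= 0):
        raise ValueError("aggregated residual variance non-positive for some feature")
    return np.sqrt(sigma_sq)


def site_local_eb(
    site_features: FeatureTable,
    site_covariates: CovariateTable,
    broadcast: ServerBroadcast,
) -> LocalEBMessage:
    """Standardize with the global parameters and shrink the site's own
    effects by single-group empirical Bayes (hyperpriors from the site's own
    moments across features)."""
    if broadcast.sigma_global is None:
        raise ValueError("broadcast lacks sigma_global; run the RSS round first")
    site = site_features.site_ids[0]
    if site not in broadcast.gamma_hat_site:
        raise KeyError(f"site {site!r} is not registered with the server")
    if site_features.n_samples < 2:
        raise ValueError(f"site {site!r}: need >= 2 samples")
    std = StandardizationModel(
        alpha=broadcast.alpha_global,
        beta=broadcast.beta_global,
        sigma=broadcast.sigma_global,
        gamma_hat=broadcast.gamma_hat_site[site][None, :],
        site_index=[site],
        site_counts=np.array([site_features.n_samples]),
    )
    z = standardize(site_features, site_covariates, std)
    eb = empirical_bayes_shrink(z, np.zeros(site_features.n_samples, dtype=int))
    return LocalEBMessage(
        site_id=site,
        gamma_star=eb.gamma_star[0],
        delta_star_sq=eb.delta_star_sq[0],
    )


def server_cluster_aggregate(
    local_eb_messages: list[LocalEBMessage], cluster_of_site: dict
) -> EBEstimates:
    """Cluster-wise parameters as unweighted means of member sites' local
    empirical Bayes estimates (delta is averaged on the delta^2 scale)."""
    missing = [m.site_id for m in local_eb_messages if m.site_id not in cluster_of_site]
    if missing:
        raise KeyError(f"sites without a cluster: {missing}")
    clusters = sorted(set(cluster_of_site.values()))
    members = {c: [] for c in clusters}
    for msg in local_eb_messages:
        members[cluster_of_site[msg.site_id]].append(msg)
    empty = [c for c in clusters if not members[c]]
    if empty:
        raise ValueError(f"cluster(s) with zero reporting members: {empty}")
    gamma = np.vstack(
        [np.mean([m.gamma_star for m in members[c]], axis=0) for c in clusters]
    )
    delta_sq = np.vstack(
        [np.mean([m.delta_star_sq for m in members[c]], axis=0) for c in clusters]
    )
    return EBEstimates(
        gamma_star=gamma,
        delta_star_sq=delta_sq,
        group_labels=list(clusters),
        iterations=1,
        converged=True,
    )


def _harmonize_with_cluster(
    features: FeatureTable,
    covariates: CovariateTable,
    model: HarmonizationModel,
    cluster_index: int,
) -> FeatureTable:
    z = standardize(features, covariates, model.standardization)
    groups = np.full(features.n_samples, cluster_index, dtype=int)
    return apply_harmonization(z, covariates, model.standardization, model.eb, groups)


def unseen_site_join(
    new_site_features: FeatureTable,
    new_site_covariates: CovariateTable,
    model: HarmonizationModel,
) -> FeatureTable:
    """Harmonize a site that never took part in training.

    The site fits its local OLS, derives gamma_hat_i against the stored
    global intercepts, and the trained parameter-space K-means assigns ONE
    cluster index to the whole site; the stored cluster parameters then
    harmonize its data.  Nothing is re-estimated server-side.
    """
    if model.mode not in ("fed-cluster", "fed-combat"):
        raise ValueError(
            f"unseen-site join requires a distributed model, got mode {model.mode!r}"
        )
    if model.mode == "fed-combat":
        raise ValueError(
            "retraining-free join requires cluster mode; the per-site baseline "
            "cannot place a new site"
        )
    if list(new_site_covariates.covariate_names) != list(model.covariate_names):
        raise ValueError(
            f"covariate schema mismatch: model expects {model.covariate_names}"
        )
    if new_site_features.n_features != model.standardization.n_features:
        raise ValueError("feature count mismatch with trained model")
    msg = site_local_fit(new_site_features, new_site_covariates)
    gamma = msg.alpha_local - model.standardization.alpha
    vec = _site_parameter_vector(msg, gamma)
    c = int(model.cluster_model.assign(vec[None, :])[0])
    return _harmonize_with_cluster(new_site_features, new_site_covariates, model, c)


def _split_by_site(features: FeatureTable, covariates: CovariateTable):
    for site in features.site_labels():
        rows = features.site_ids == site
        ft = FeatureTable(
            sample_ids=features.sample_ids[rows],
            site_ids=features.site_ids[rows],
            values=features.values[rows],
            feature_names=list(features.feature_names),
        )
        cv = CovariateTable(covariates.values[rows], list(covariates.covariate_names))
        yield site, rows, ft, cv


def run_distributed(
    features: FeatureTable,
    covariates: CovariateTable,
    n_clusters: int,
    seed: int = 0,
    cluster: bool = True,
):
    """Execute the whole federated protocol in-process.

    With ``cluster=False`` the protocol runs the Distributed ComBat
    baseline: the clustering step is skipped and every site keeps its own
    parameters (equivalently, C = M with site-identity clusters).

    Returns ``(model, harmonized, round_log)`` where ``harmonized`` stacks
    every site's locally harmonized output in the original row order.
    """
    log = RoundLog()
    sites = list(_split_by_site(features, covariates))
    m = len(sites)
    if not cluster:
        n_clusters = m

    # round 1: local OLS up, global parameters + clustering down
    messages = []
    for site, _, ft, cv in sites:
        msg = site_local_fit(ft, cv)
        log.add("local-ols", "site->server", site, _payload_size(msg.payload_arrays()))
        messages.append(msg)
    if cluster:
        broadcast = server_initialize(messages, n_clusters, seed)
    else:
        broadcast = _server_initialize_site_identity(messages, seed)
    down_size = _payload_size(
        [broadcast.alpha_global, broadcast.beta_global, broadcast.cluster_model.centroids]
    ) + features.n_features  # per-site gamma_hat
    for site, *_ in sites:
        log.add("globals", "server->site", site, down_size)

    # round 2 (half-round): RSS up, sigma down
    rss = {}
    for site, _, ft, cv in sites:
        r = site_local_rss(ft, cv, broadcast)
        log.add("rss", "site->server", site, r.size)
        rss[site] = r
    broadcast.sigma_global = server_aggregate_sigma(
        rss, {msg.site_id: msg.n_samples for msg in messages}
    )
    for site, *_ in sites:
        log.add("sigma", "server->site", site, broadcast.sigma_global.size)

    # round 3: local EB up, cluster-wise parameters down
    eb_msgs = []
    for site, _, ft, cv in sites:
        msg = site_local_eb(ft, cv, broadcast)
        log.add("local-eb", "site->server", site, _payload_size(msg.payload_arrays()))
        eb_msgs.append(msg)
    broadcast.eb_cluster = server_cluster_aggregate(eb_msgs, broadcast.cluster_of_site)
    for site, *_ in sites:
        log.add(
            "cluster-params",
            "server->site",
            site,
            _payload_size([broadcast.eb_cluster.gamma_star, broadcast.eb_cluster.delta_star_sq]),
        )

    std = StandardizationModel(
        alpha=broadcast.alpha_global,
        beta=broadcast.beta_global,
        sigma=broadcast.sigma_global,
        gamma_hat=np.vstack([broadcast.gamma_hat_site[s] for s, *_ in sites]),
        site_index=[s for s, *_ in sites],
        site_counts=np.array([msg.n_samples for msg in messages]),
    )
    model = HarmonizationModel(
        standardization=std,
        cluster_model=broadcast.cluster_model,
        eb=broadcast.eb_cluster,
        mode="fed-cluster" if cluster else "fed-combat",
        covariate_names=list(covariates.covariate_names),
        feature_names=list(features.feature_names),
        site_cluster_map={str(s): int(c) for s, c in broadcast.cluster_of_site.items()},
    )

    # final local harmonization with the received cluster parameters
    out = np.empty_like(features.values)
    for site, rows, ft, cv in sites:
        harm = _harmonize_with_cluster(ft, cv, model, broadcast.cluster_of_site[site])
        out[rows] = harm.values
    harmonized = FeatureTable(
        sample_ids=features.sample_ids,
        site_ids=features.site_ids,
        values=out,
        feature_names=list(features.feature_names),
    )
    return model, harmonized, log


def _server_initialize_site_identity(
    messages: list[SiteMessage], seed: int
) -> ServerBroadcast:
    """Baseline server state: each site is its own singleton cluster."""
    alpha_global = np.mean([m.alpha_local for m in messages], axis=0)
    beta_global = np.mean([m.beta_local for m in messages], axis=0)
    gamma_hat_site = {m.site_id: m.alpha_local - alpha_global for m in messages}
    points = np.vstack(
        [_site_parameter_vector(m, gamma_hat_site[m.site_id]) for m in messages]
    )
    cm = ClusterModel(
        n_clusters=len(messages),
        centroids=points,
        space_tag="site-parameters",
        seed=seed,
    )
    cluster_of_site = {m.site_id: k for k, m in enumerate(messages)}
    return ServerBroadcast(
        alpha_global=alpha_global,
        beta_global=beta_global,
        gamma_hat_site=gamma_hat_site,
        cluster_model=cm,
        cluster_of_site=cluster_of_site,
    )
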