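"""Feature-wise location/scale modelling and empirical Bayes shrinkage.

This module implements the shared core of every ComBat-style harmonization
variant in the package: the feature-wise ordinary-least-squares fit of the
location/scale (L/S) model

    y_ijg = alpha_g + X_ij . beta_g + gamma_ig + delta_ig * eps_ijg,

feature-wise standardization, method-of-moments hyperprior estimation for
the additive (normal prior) and multiplicative (inverse-gamma prior) batch
effects, the iterative empirical Bayes estimator of the shrunken effects
(gamma*, delta*^2), and the final harmonization map.  Classic ComBat
(`fit_combat`) is the composition of these steps with grouping = site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureTable",
    "CovariateTable",
    "StandardizationModel",
    "StandardizedMatrix",
    "EBHyperpriors",
    "EBEstimates",
    "fit_feature_wise_ols",
    "standardize",
    "estimate_hyperpriors",
    "empirical_bayes_shrink",
    "apply_harmonization",
    "fit_combat",
    "transform_sites",
]

_ZERO_VAR_TOL = 1e-12


@dataclass
class FeatureTable:
    """An n x G matrix of continuous measurements with per-sample site labels."""

    sample_ids: np.ndarray
    site_ids: np.ndarray
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.site_ids = np.asarray(self.site_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (samples x features)")
        n, g = self.values.shape
        if n < 1 or g < 1:
            raise ValueError("need at least one sample and one feature")
        if len(self.sample_ids) != n or len(self.site_ids) != n:
            raise ValueError("sample_ids/site_ids length must match row count")
        if len(self.feature_names) != g:
            raise ValueError("feature_names length must match column count")
        if len(np.unique(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def site_labels(self) -> list:
        """Distinct site labels in first-appearance order."""
        _, idx = np.unique(self.site_ids, return_index=True)
        return [self.site_ids[i] for i in sorted(idx)]


@dataclass
class CovariateTable:
    """Biological covariates aligned row-for-row with a FeatureTable.

    P = 0 (an n x 0 matrix) is allowed and selects the intercept-only model.
    """

    values: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariate values must be 2-D (samples x covariates)")
        if len(self.covariate_names) != self.values.shape[1]:
            raise ValueError("covariate_names length must match column count")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("covariate values contain non-finite entries")

    @classmethod
    def empty(cls, n: int) -> "CovariateTable":
        return cls(np.empty((n, 0)), [])

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizationModel:
    """Feature-wise L/S regression fit: intercepts, slopes, pooled scale and
    raw per-site additive effects under the sample-size-weighted zero-sum
    constraint sum_i (N_i/N) gamma_hat[i, g] = 0."""

    alpha: np.ndarray          # (G,)
    beta: np.ndarray           # (G, P)
    sigma: np.ndarray          # (G,) positive
    gamma_hat: np.ndarray      # (M, G)
    site_index: list           # ordered site labels, length M
    site_counts: np.ndarray    # (M,) positive ints

    @property
    def n_features(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[1]


@dataclass
class StandardizedMatrix:
    """Residual matrix z = (y - alpha - X beta) / sigma; site and cluster
    effects remain in z and are what empirical Bayes estimates."""

    z: np.ndarray
    sample_ids: np.ndarray
    site_ids: np.ndarray
    feature_names: list[str]


@dataclass
class EBHyperpriors:
    """Method-of-moments prior parameters for one group (site or cluster):
    gamma ~ N(gamma_bar, tau_bar_sq), delta^2 ~ InvGamma(lambda_bar, theta_bar)."""

    gamma_bar: float
    tau_bar_sq: float
    lambda_bar: float
    theta_bar: float
    degenerate: bool = False


@dataclass
class EBEstimates:
    """Converged empirical Bayes estimates per group and feature."""

    gamma_star: np.ndarray       # (n_groups, G)
    delta_star_sq: np.ndarray    # (n_groups, G) positive
    group_labels: list
    iterations: int
    converged: bool

    def group_position(self, label) -> int:
        try:
            return self.group_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown group label: {label!r}") from None


def _design_matrix(features: FeatureTable, covariates: CovariateTable):
    """Site one-hot block plus covariate block; site labels in first-appearance order."""
    labels = features.site_labels()
    site_pos = {lab: k for k, lab in enumerate(labels)}
    n = features.n_samples
    m = len(labels)
    dummies = np.zeros((n, m))
    for j, s in enumerate(features.site_ids):
        dummies[j, site_pos[s]] = 1.0
    design = np.hstack([dummies, covariates.values])
    return design, labels


def fit_feature_wise_ols(
    features: FeatureTable,
    covariates: CovariateTable,
    allow_single_site: bool = False,
) -> StandardizationModel:
    """Fit the L/S mean structure by feature-wise OLS.

    One-hot site coding absorbs the intercept; the intercept alpha_g is
    recovered afterwards as the sample-size-weighted mean of the per-site
    levels, which enforces sum_i (N_i/N) gamma_hat[i, g] = 0 exactly.
    sigma_g is the root mean squared residual over all n samples (the
    residual subtracts the site effect).
    """
    if covariates.values.shape[0] != features.n_samples:
        raise ValueError("covariate row count does not match feature table")
    design, labels = _design_matrix(features, covariates)
    m = len(labels)
    p = covariates.n_covariates
    if m < 2 and not allow_single_site:
        raise ValueError("need >= 2 sites (pass allow_single_site=True to override)")
    n = features.n_samples
    if n <= p + m:
        raise ValueError(
            f"under-determined fit: n={n} samples but {m} sites + {p} covariates"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, labels, covariates.covariate_names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    coef, *_ = np.linalg.lstsq(design, features.values, rcond=None)
    site_levels = coef[:m, :]                      # (M, G)
    beta = coef[m:, :].T                           # (G, P)
    counts = np.array([int(np.sum(features.site_ids == s)) for s in labels])
    weights = counts / counts.sum()
    alpha = weights @ site_levels                  # (G,)
    gamma_hat = site_levels - alpha                # (M, G)

    resid = features.values - design @ coef
    sigma_sq = np.mean(resid**2, axis=0)
    zero_var = np.flatnonzero(sigma_sq <= _ZERO_VAR_TOL)
    if zero_var.size:
        names = [features.feature_names[g] for g in zero_var]
        raise ValueError(f"zero residual variance for feature(s): {names}")

    return StandardizationModel(
        alpha=alpha,
        beta=beta,
        sigma=np.sqrt(sigma_sq),
        gamma_hat=gamma_hat,
        site_index=labels,
        site_counts=counts,
    )


def _collinear_columns(design, site_labels, covariate_names) -> list[str]:
    names = [f"site[{s}]" for s in site_labels] + list(covariate_names)
    bad, rank = [], 0
    for k in range(design.shape[1]):
        r = np.linalg.matrix_rank(design[:, : k + 1])
        if r == rank:
            bad.append(names[k])
        rank = r
    return bad


def standardize(
    features: FeatureTable,
    covariates: CovariateTable,
    model: StandardizationModel,
) -> StandardizedMatrix:
    """z[j, g] = (y[j, g] - alpha_g - X_j . beta_g) / sigma_g.

    The additive site effect is deliberately *not* subtracted: z is the
    input to empirical Bayes, which estimates it.
    """
    if covariates.n_covariates != model.n_covariates:
        raise ValueError(
            f"covariate schema mismatch: model expects P={model.n_covariates}, "
            f"got P={covariates.n_covariates}"
        )
    if features.n_features != model.n_features:
        raise ValueError(
            f"feature count mismatch: model has G={model.n_features}, "
            f"data has G={features.n_features}"
        )
    if np.any(model.sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    mean = model.alpha + covariates.values @ model.beta.T
    z = (features.values - mean) / model.sigma
    return StandardizedMatrix(
        z=z,
        sample_ids=features.sample_ids,
        site_ids=features.site_ids,
        feature_names=features.feature_names,
    )


def estimate_hyperpriors(
    gamma_hat_group: np.ndarray,
    delta_hat_sq_group: np.ndarray,
) -> EBHyperpriors:
    """Method-of-moments hyperpriors for one group, pooling across features.

    Normal prior on gamma: sample mean / variance of gamma_hat over features.
    Inverse-gamma prior on delta^2: with m and s^2 the mean and variance of
    the raw delta_hat^2 over features,

        lambda_bar = (m^2 + 2 s^2) / s^2,   theta_bar = (m^3 + m s^2) / s^2,

    which are the moment-matching solutions of E = theta/(lambda-1),
    Var = theta^2 / ((lambda-1)^2 (lambda-2)).
    """
    g_hat = np.asarray(gamma_hat_group, dtype=float)
    d_hat = np.asarray(delta_hat_sq_group, dtype=float)
    if g_hat.size < 2:
        raise ValueError("hyperpriors undefined for single feature")
    if np.any(d_hat <= 0):
        raise ValueError("delta_hat_sq must be strictly positive")
    gamma_bar = float(np.mean(g_hat))
    tau_bar_sq = float(np.var(g_hat, ddof=1))
    m = float(np.mean(d_hat))
    s2 = float(np.var(d_hat, ddof=1))
    if s2 <= 0:
        raise ValueError("degenerate inverse-gamma fit: zero variance of delta_hat_sq")
    lambda_bar = (m * m + 2.0 * s2) / s2
    theta_bar = (m**3 + m * s2) / s2
    degenerate = tau_bar_sq <= 0
    if lambda_bar <= 1.0:
        warnings.warn(
            f"lambda_bar={lambda_bar:.4g} <= 1: inverse-gamma prior has no mean; "
            "empirical Bayes denominator may be non-positive for small groups",
            RuntimeWarning,
        )
    if degenerate:
        warnings.warn("zero variance of gamma_hat across features", RuntimeWarning)
    return EBHyperpriors(gamma_bar, tau_bar_sq, lambda_bar, theta_bar, degenerate)


def empirical_bayes_shrink(
    z: StandardizedMatrix,
    group_of_sample: np.ndarray,
    hyperpriors: Mapping[object, EBHyperpriors] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    ddof: int = 0,
) -> EBEstimates:
    """Iterate the coupled empirical Bayes updates to a fixed point per group.

    For each group with n samples of standardized data, alternate

        gamma* = (n tau_bar^2 gamma_hat + delta*^2 gamma_bar)
                 / (n tau_bar^2 + delta*^2)
        delta*^2 = (theta_bar + 1/2 sum_j (z_jg - gamma*)^2)
                   / (n/2 + lambda_bar - 1)

    from gamma* = group mean of z, delta*^2 = group variance of z, until the
    maximum relative change falls below ``tol`` or ``max_iter`` sweeps.

    ``ddof=0`` (default) uses the n-denominator sample variance for the raw
    delta_hat^2, which keeps the update stable for small groups; ``ddof=1``
    switches to the unbiased variant.

    If ``hyperpriors`` is None they are estimated per group from the group's
    own moments across features.
    """
    groups = np.asarray(group_of_sample)
    if groups.shape[0] != z.z.shape[0]:
        raise ValueError("group assignment length must match sample count")
    _, first = np.unique(groups, return_index=True)
    labels = [groups[i] for i in sorted(first)]

    n_g = len(labels)
    G = z.z.shape[1]
    gamma_star = np.empty((n_g, G))
    delta_star_sq = np.empty((n_g, G))
    total_iters = 0
    all_converged = True

    for k, lab in enumerate(labels):
        rows = z.z[groups == lab]
        n = rows.shape[0]
        if n < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        g_hat = rows.mean(axis=0)
        d_hat = rows.var(axis=0, ddof=ddof)
        hp = (
            hyperpriors[lab]
            if hyperpriors is not None
            else estimate_hyperpriors(g_hat, d_hat)
        )
        denom = 0.5 * n + hp.lambda_bar - 1.0
        if denom <= 0:
            raise ValueError(
                f"group {lab!r}: n/2 + lambda_bar - 1 = {denom:.4g} <= 0; "
                "empirical Bayes update undefined"
            )
        s1 = rows.sum(axis=0)
        s2 = (rows**2).sum(axis=0)
        g_star = g_hat.copy()
        d_star = np.maximum(d_hat, _ZERO_VAR_TOL)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (n * hp.tau_bar_sq * g_hat + d_star * hp.gamma_bar) / (
                n * hp.tau_bar_sq + d_star
            )
            ss = s2 - 2.0 * g_new * s1 + n * g_new**2
            d_new = (hp.theta_bar + 0.5 * ss) / denom
            change = max(
                np.max(np.abs(g_new - g_star) / np.maximum(np.abs(g_star), 1e-12)),
                np.max(np.abs(d_new - d_star) / np.maximum(np.abs(d_star), 1e-12)),
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"empirical Bayes did not converge for group {lab!r} "
                f"after {max_iter} sweeps",
                RuntimeWarning,
            )
            all_converged = False
        total_iters = max(total_iters, it)
        gamma_star[k] = g_star
        delta_star_sq[k] = d_star

    return EBEstimates(
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        group_labels=labels,
        iterations=total_iters,
        converged=all_converged,
    )


def apply_harmonization(
    z: StandardizedMatrix,
    covariates: CovariateTable,
    model: StandardizationModel,
    eb: EBEstimates,
    group_of_sample: np.ndarray,
) -> FeatureTable:
    """Map standardized data back to the feature scale with batch effects removed:

        y*[j, g] = sigma_g / delta*(c, g) * (z[j, g] - gamma*(c, g))
                   + alpha_g + X_j . beta_g
    """
    groups = np.asarray(group_of_sample)
    if np.any(eb.delta_star_sq <= 0):
        raise ValueError("delta_star_sq must be strictly positive")
    pos = np.array([eb.group_position(lab) for lab in groups])
    g_star = eb.gamma_star[pos]                    # (n, G)
    d_star = np.sqrt(eb.delta_star_sq[pos])        # (n, G)
    mean = model.alpha + covariates.values @ model.beta.T
    values = model.sigma * (z.z - g_star) / d_star + mean
    return FeatureTable(
        sample_ids=z.sample_ids,
        site_ids=z.site_ids,
        values=values,
        feature_names=list(z.feature_names),
    )


def fit_combat(
    features: FeatureTable,
    covariates: CovariateTable,
    eb_tol: float = 1e-6,
    eb_max_iter: int = 500,
):
    """Classic ComBat: the empirical Bayes pipeline with grouping = site.

    Equivalent to the cluster variant with C = M clusters and the assignment
    fixed to site identity.  Returns a HarmonizationModel in ``combat`` mode.
    """
    from .cluster_combat import HarmonizationModel

    counts = {s: int(np.sum(features.site_ids == s)) for s in features.site_labels()}
    if len(counts) < 2:
        raise ValueError("classic ComBat needs >= 2 sites")
    small = [s for s, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"sites with fewer than 2 samples: {small}")
    std_model = fit_feature_wise_ols(features, covariates)
    z = standardize(features, covariates, std_model)
    eb = empirical_bayes_shrink(z, features.site_ids, tol=eb_tol, max_iter=eb_max_iter)
    return HarmonizationModel(
        standardization=std_model,
        cluster_model=None,
        eb=eb,
        mode="combat",
        covariate_names=list(covariates.covariate_names),
        feature_names=list(features.feature_names),
    )


def transform_sites(features: FeatureTable, covariates: CovariateTable, model) -> FeatureTable:
    """Harmonize data whose site labels are all known to a site-grouped model."""
    known = set(map(str, model.eb.group_labels))
    unknown = sorted({str(s) for s in features.site_ids} - known)
    if unknown:
        raise KeyError(f"unknown site label(s): {unknown}")
    z = standardize(features, covariates, model.standardization)
    # group labels may have round-tripped through text serialization
    lut = {str(lab): lab for lab in model.eb.group_labels}
    groups = np.array([lut[str(s)] for s in features.site_ids], dtype=object)
    return apply_harmonization(z, covariates, model.standardization, model.eb, groups)
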