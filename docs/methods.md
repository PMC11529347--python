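# Methods

## Model

Every variant in the package rests on the location/scale model for feature
`g` of sample `j` at site `i`:

    y_ijg = α_g + X_ij β_g + γ_ig + δ_ig ε_ijg,   ε_ijg ~ N(0, σ_g²).

`fit_feature_wise_ols` estimates the mean structure with one-hot site
coding plus the covariate block. Because the site dummies span the
intercept, the design is solved without an explicit intercept column and
α̂_g is recovered afterwards as the site-count-weighted mean of the per-site
levels, which enforces the identifiability constraint Σ_i (N_i/N) γ̂_ig = 0
exactly (the weighted convention; the residual that defines σ̂_g subtracts
the site effect, so σ̂_g² is the mean squared residual over all N samples).
The design matrix is shared by all features, so a single `lstsq` call fits
every feature at once.

Standardization divides the covariate-adjusted residual by σ̂_g and
deliberately leaves the site/cluster effect in place — that effect is what
empirical Bayes then estimates, group-wise, from

    γ*  = (n τ̄² γ̂ + δ*² γ̄) / (n τ̄² + δ*²)
    δ*² = (θ̄ + ½ Σ_j (Z_jg − γ*)²) / (n/2 + λ̄ − 1)

iterated to a joint fixed point. Hyperpriors come from method of moments
across features: (γ̄, τ̄²) are the sample mean/variance (ddof=1) of the
group means of Z, and with m, s² the mean/variance of the raw group
variances, λ̄ = (m²+2s²)/s², θ̄ = (m³+m s²)/s² — the moment-matching
solutions for the inverse-gamma prior. γ* is always a convex combination of
γ̄ and the group mean, which the tests assert as an invariant.

Numerical choices: iteration starts at the group sample moments of Z;
updates alternate γ* then δ*²; stopping is max elementwise relative change
< 1e-6 (500 sweeps cap; `fit_combat` exposes the tolerance for
high-precision comparisons). The raw group variance uses the n-denominator
(ddof=0) so the fixed point stays stable for small groups; ddof=1 is
switchable. A non-positive EB denominator (possible when the moment
estimate gives λ̄ ≤ 1 with a tiny group) raises rather than clamps —
clamping would silently distort δ*. Groups of size 1 and zero-variance
features are rejected at fit time.

## Cluster variant

`fit_cluster_combat` runs K-means (k-means++, 10 restarts, recorded seed)
on the raw sample feature vectors, assigning a cluster index per *sample* —
samples from one site may land in different clusters. Clustering precedes
standardization, matching the procedure the package implements; clustering
on standardized residuals instead is untested here. Assignment is argmin
Euclidean distance with ties broken toward the lowest index, so replay is
deterministic. Empirical Bayes then pools each cluster's samples, producing
G·C parameter pairs. An unseen site's samples are assigned to the nearest
stored centroid and harmonized with the trained parameters; nothing is
refit. Clusters that end with fewer than 2 members trigger a bounded
reseed-and-retry, then an error. The CLI default C=5 reflects a typical
multi-scanner consortium; C is always user-set and the benchmark uses each
preset's true cluster count.

## Federated variant

Sites never transmit sample-level arrays; every payload scales with G, not
N_i. Round 1: each site sends its local OLS intercepts and slopes. The
server averages them *unweighted* into (α̂_g, β̂_g) (a sample-size-weighted
option exists behind a flag), defines each site's additive effect as
γ̂_ig = α̂_ig − α̂_g — the identifiable reading of a "locally estimated"
site effect, since a lone intercept cannot separate α from γ — and fits
K-means to the M concatenated vectors [α̂_i ‖ vec(β̂_i) ‖ γ̂_i]. The vector
includes both α̂_i and γ̂_i even though they differ by a constant; the
redundancy doubles the intercept signal's weight and is kept deliberately.
No scaling is applied before clustering (raw Euclidean distance). Round 2:
sites send per-feature residual sums of squares against the global mean
structure, from which the server assembles σ̂_g² = Σ_i RSS_ig / N — the
literal pooled-scale definition from aggregates only. Round 3: each site
standardizes with the globals, runs single-group empirical Bayes with
hyperpriors from its own cross-feature moments, and sends (γ*_i, δ*²_i);
the server averages these unweighted within each cluster, averaging on the
δ*² scale (the quantity EB actually estimates). An unseen site joins by
sending its local OLS fit; the whole site receives one cluster index.
With C = M the protocol reduces exactly to a per-site federated ComBat
baseline, which the tests assert.

## Synthetic data

The generator draws α_g ~ N(0, sd_alpha²), β_pg ~ N(0, sd_beta²), per
cluster γ_cg ~ N(0, sd_gamma²) and δ_cg ~ U(delta_low, delta_high), then
y_ijg ~ N(α_g + X_ij β_g + γ_cg, δ_cg² σ_g²). Binary class labels are
encoded in the covariates: X_jp ~ N(+0.5, 0.5²) for positive samples and
N(−0.5, 0.5²) for negative (mean ±0.5 with *standard deviation* 0.5,
keeping covariate signal-to-noise at 2 so downstream accuracy is high but
imperfect). Labels are exactly balanced within each site; sites join
clusters in contiguous blocks. The noiseless signal α + Xβ is returned as
ground truth. Defaults — sd_alpha=1, sd_beta=1, sd_gamma=2, δ ~ U(0.5, 2),
σ_g=1 — give a strong batch effect (unharmonized reconstruction RMSE ≈ 2.3
vs ≈ 1.5 harmonized) while keeping clusters imperfectly separable, as real
scanner groups are. σ_g is fixed rather than drawn per feature;
per-feature scales are configurable. The five presets scale sites,
per-site samples and features together (20/20/20 … 40/40/50, five sites
per cluster, five covariates).

What the generator does *not* emulate: non-Gaussian noise, covariate
imbalance across sites, nonlinear covariate effects, longitudinal
structure, or site effects that deviate from exact within-cluster sharing.
Passing tests therefore demonstrate correctness of the estimation machinery
under its own model assumptions, not robustness to their violation.

## Evaluation protocol

The benchmark holds out 30% of *sites* (the unseen-site reading of a 70/30
split; a sample-level split exists behind a flag). Methods that cannot
absorb an unseen site — classic and federated ComBat — are refit on the
pooled train+test sites, while the downstream predictor only ever trains on
training-site rows; cluster methods fit on training sites and transform the
held-out sites with no refit. Reported cells are mean and variance over
seeds. Downstream models are logistic regression (accuracy) and ordinary
least squares (MAE); the batch probe is a multinomial logistic regression
over repeated random 70/30 sample splits; significant-feature counting uses
the two-sided t-test on each univariate slope, averaged over split seeds.

One protocol asymmetry is worth naming: because the retrained baselines are
scored on the very rows they were refit on, their per-site effects absorb
part of those rows' realized noise (the EB shrinkage weight under the
default separation is ~1/47, so absorption is nearly complete), deflating
their apparent reconstruction error by a few percent. On fresh residual
draws from the same held-out sites the cluster variant reconstructs at
least as well — the suite asserts this as a property.

## Problem sizes

Default test and benchmark runs use the bundled presets (400–1600 samples,
20–50 features) with 10–30 seeds, chosen as the smallest sizes at which the
between-method orderings are stable; the acceptance script completes in
well under a minute on one core.

## Limitations

K-means on raw samples can merge clusters whose additive effects happen to
lie close together (this is a property of the objective, not of the
restarts), which degrades parameter recovery on such draws; C is taken as
given rather than selected automatically; message passing is simulated
in-process with explicit payload types rather than over sockets; and model
documents are versioned JSON with no migration between schema versions.
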