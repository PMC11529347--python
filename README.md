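# clustercombat

Batch-effect harmonization for multi-site tabular measurements — classic
ComBat, a cluster-aware variant that generalizes to previously unseen sites
without retraining, and federated versions of both in which sites exchange
only parameter vectors, never raw samples.

## The problem

Continuous features pooled across acquisition sites (scanners, labs,
protocols) carry systematic site distortions that swamp the biological
signal of interest. The standard remedy models each feature `g` of sample
`j` at site `i` with a location/scale (L/S) decomposition

```
y_ijg = α_g + X_ij β_g + γ_ig + δ_ig ε_ijg ,    ε_ijg ~ N(0, σ_g²)
```

where `X_ij` are biological covariates (age, sex, …), `γ_ig` is the additive
and `δ_ig` the multiplicative site effect. ComBat estimates `(α, β, σ)` by
feature-wise OLS, standardizes `Z_ijg = (y_ijg − α̂_g − X_ij β̂_g)/σ̂_g`, and
shrinks the per-site effects by empirical Bayes under a normal prior on γ
and an inverse-gamma prior on δ², with hyperpriors fit across features by
method of moments. Harmonized values are

```
y*_ijg = σ̂_g / δ*_ig · (Z_ijg − γ*_ig) + α̂_g + X_ij β̂_g .
```

Two limitations motivate the cluster variant. Site-wise parameters must be
estimated from each site's own (often small) sample, and a site absent from
training cannot be harmonized at all without refitting on every
participating site. When groups of sites share their distortion (same
scanner vendor, same kit lot), pooling them into `C ≤ M` clusters found by
K-means yields `G·C` instead of `G·M` parameters, each estimated from more
samples — and a new site is harmonized by simply assigning it to the
nearest existing cluster.

In the federated setting no raw data may leave a site. Each site fits its
feature-wise OLS locally and ships only `(α̂_i, β̂_i)`; the server averages
them into global parameters, clusters the per-site parameter vectors
(cluster structure in feature space survives into parameter space),
assembles the pooled scale from per-site residual sums of squares, and
averages the sites' locally shrunken effects within each cluster.

## Worked example

Train on 14 of 20 synthetic sites whose batch effects are shared within 4
clusters, then harmonize the 6 held-out sites with no re-estimation:

```python
from clustercombat import (generate_dataset, preset_config, split_by_sites,
                           fit_cluster_combat, transform_unseen)
from clustercombat.synthetic_data import subset
from clustercombat.evaluation import rmse_reconstruction, downstream_metric

ds = generate_dataset(preset_config("data1", seed=7))
train_mask, test_mask = split_by_sites(ds, 0.7, seed=7)
train, test = subset(ds, train_mask), subset(ds, test_mask)

model = fit_cluster_combat(train.features, train.covariates, n_clusters=4, seed=7)
harmonized = transform_unseen(test.features, test.covariates, model)

print(rmse_reconstruction(test.features, test.ground_truth))   # 2.191
print(rmse_reconstruction(harmonized, test.ground_truth))      # 1.586
```

Reconstruction RMSE against the noiseless signal `α + Xβ` drops from 2.191
to 1.586 on sites the model never saw, using only `G·C = 20·4` stored
parameter pairs for 14 training sites; a downstream logistic regression on
the harmonized features classifies the covariate-encoded labels at 0.950
accuracy. The same workflow is available from the shell:

```
clustercombat simulate --preset data1 --seed 7 --out sim/
clustercombat fit --input sim/features.csv --covariates x0,x1,x2,x3,x4 \
    --clusters 4 --seed 7 --out model.json
clustercombat transform --input new_site.csv --model model.json --out harmonized.csv
```

`fedrun` / `join` run the federated protocol and let an unseen site enroll
by sending only its local OLS parameters.

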