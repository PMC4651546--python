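# cooccupancy

Two-species hierarchical co-occurrence occupancy modeling for camera-trap
detection histories, built around a winter bobcat–snowshoe hare system: a
prey species whose weekly occupancy follows landcover composition, a
predator whose occupancy is conditional on prey presence with road/water
covariates at two spatial scales, and imperfect daily detection at baited
camera stations.

It is written for quantitative ecologists who want the full Bayesian
workflow for this model family — simulation, MCMC fitting with covariate
selection, posterior-predictive model checking, and co-occurrence
contrasts — as an importable library with reproducible, seeded analyses,
instead of a one-off BUGS script.

## The model

For cell *i* and week *t* (64 cells × 11 weeks at study dimensions):

    Z^H_{i,t} ~ Bernoulli(μ^H_{i,t})                        prey occupancy
    logit μ^H = b_H + Σ_k w_k β_k x_k(i) + ε^H_{i,t}

    Z^B_{i,t} ~ Bernoulli(μ^B_{i,t})                        predator occupancy
    μ^B = Z^H · μ1 + (1 − Z^H) · μ0                         conditional mixture
    logit μ1 = b1 + Σ_k w_k θ1_k u_k(i) + ε^B_{i,t}
    logit μ0 = b0 + Σ_k w_k θ0_k u_k(i) + ε^B_{i,t}

    Y^H_{i,t} ~ Binomial(K_{i,t}, p^H_{i,t} · Z^H_{i,t})    detection
    Y^B_{i,t} ~ Binomial(K_{i,t}, p^B_i · Z^B_{i,t})

with x the nine scaled landcover proportions, u the five scaled road/water
covariates (cell scale, eight-cell neighborhood scale, distance to water),
w_k ~ Bernoulli(1/2) inclusion indicators (Kuo–Mallick variable selection),
ε ~ N(0, σ²) cell-week random effects, and K ≤ 7 camera-operating days.
Inference is Metropolis-within-Gibbs with exact latent-occupancy and
conjugate detection/variance updates; model checking uses posterior-
predictive Bayesian p-values on weekly detection totals; co-occurrence is
summarized by posterior contingency tables and conjugate-beta contrasts
Pr(θ₁ > θ₂).  See `docs/methods.md` for the full account.

## Worked example

```python
from cooccupancy import (MCMCConfig, TrueParams, generate_landscape,
                         scale_covariates, simulate_dataset, run_mcmc)
from cooccupancy.io import summarize_posterior

grid, raw = generate_landscape(8, 8, seed=1, spatial_smoothness=0.3)
cov = scale_covariates(raw, grid)
history, latent, detection = simulate_dataset(cov, TrueParams(), n_weeks=11, seed=2)
samples = run_mcmc(history, cov, MCMCConfig.test_scale(seed=11))
tables = summarize_posterior(samples)
print(tables["parameters"].loc[["hare intercept", "hare_grassland",
                                "absent_road_cell", "absent_road_neigh"]]
      [["mean_included", "lo95", "hi95", "inclusion_prob"]].round(3))
```

Running the equivalent pipeline (`analysis/01` then `analysis/02`) prints,
among the full parameter table:

```
parameter          mean_included   lo95   hi95  inclusion_prob
hare intercept            -1.169 -1.446 -0.942             NaN
hare_grassland             0.659  0.441  0.904           1.000
absent_road_cell          -1.486 -2.286 -0.838           1.000
absent_road_neigh          1.150  0.717  1.670           1.000

covariates with inclusion probability > 0.5:
  ['absent_road_cell', 'absent_road_neigh', 'hare_grassland']
mean occupancy: hare 0.271, bobcat 0.063
```

The sampler recovers exactly the generating structure: the prey responds to
grassland cover (generating slope 0.41), and when prey are absent the
predator avoids roads locally (generating slope −1.04) while selecting
road-dense neighborhoods (0.83); all three effects are selected with
posterior inclusion probability 1 in this realization, and every other
candidate covariate is dropped.  The intercept and road intervals cover
their generating values; the grassland interval overshoots narrowly in
this single realization — `analysis/05` quantifies coverage across
replicates (58/60 checks at nominal 0.95 in the bundled run).  `analysis/03` shows the observation-model selection step — the
constant-detection model is rejected (Bayesian p-values 0.000/0.000)
while cell-varying detection fits (0.484/0.597) — and `analysis/04`
produces the posterior co-occurrence contingency table and the
beta-binomial contrast of predator occupancy between prey-present and
prey-absent cell-weeks.

## Layout

    src/cooccupancy/   library: landscape, model, simulate, mcmc, gof,
                       cooccurrence, io, cli
    analysis/          numbered narrative drivers (simulate → fit → GOF
                       ladder → co-occurrence → recovery); outputs in results/
    tests/             pytest suite, including end-to-end acceptance checks
    scripts/           acceptance.py (see below)

A `cooccupancy` CLI wraps the same pipeline
(`cooccupancy simulate|fit|gof|cooccur|summarize|all --seed N --outdir D`).

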