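# commocc

Hierarchical Bayesian **community occupancy modelling** for
camera-trap surveys that span several distinct areas of one landscape.

`commocc` is written for ecologists who have camera-trap detection
histories of a mammal (or similar) community from multiple survey
regions and want landscape-level answers: How many species does each
region really hold, given that some were certainly missed? What is the
average occupancy and detectability of the meta-community? Which
habitat and disturbance covariates shape occupancy, and do individual
species depart from the community-wide response?

## The model

For species slot `k`, site `i`, region `r`:

    w_kr  ~ Bernoulli(Omega_r)                        (community membership)
    z_kir | w_kr ~ Bernoulli(w_kr * psi_kir)          (occupancy)
    y_kir | z_kir ~ Binomial(effort_i, z_kir * p_kir) (detection over trap-days)

    logit(psi_kir) = beta0_kr + beta1*logmass_k + beta2_kr*dRiv_ir
                     + beta3_kr*dSettl_ir + beta4_kr*forCover_ir
    logit(p_kir)   = alpha0_kr + alpha1*logmass_k + alpha2_kr*dSettl_ir

Each region's species list is augmented to a fixed pool of `M` slots
with all-zero histories, so regional richness `N_r = sum_k w_kr`
includes the species that escaped detection. Intercepts and
site-covariate slopes are species random effects drawn from
community-level Normal hyperdistributions shared across regions; body
mass enters through community-level slopes and is itself modelled as
`logmass_kr ~ Normal(mu_mass_r, sigma_mass_r^2)`, yielding a posterior
for each region's average community body mass. Inference is by a
custom Metropolis-within-Gibbs sampler with exact updates for the
discrete latents and joint hyper moves for the hierarchical means and
SDs; see `docs/methods.md` for the full specification, priors and
validation (enumeration oracles, simulation-based calibration,
parameter recovery).

## Worked example

```python
import commocc as co

config = co.reduced_scale(seed=7)          # 3 regions x 20 sites, 5-10 trap-days
sites, truth, data, traits = co.generate_dataset(config)
print("observed richness:", {r: data.n_species(r) for r in data.regions})
print("true richness:    ", dict(zip(data.regions, truth.n_true.tolist())))

aug = co.augment(data, M=40)               # pad each region to 40 species slots
mdata = co.prepare_model_data(aug, traits)
draws = co.run_chains(
    mdata, co.PriorSpec(),
    co.McmcConfig(n_iter=6000, burn_in=2000, thin=4, n_chains=2, seed=1),
)
print(co.richness_summary(draws).to_string(index=False))
print(co.community_prob_summary(draws)[["quantity", "mean", "q2.5", "q97.5"]]
      .round(3).to_string(index=False))
```

prints

```
observed richness: {'R1': 11, 'R2': 17, 'R3': 11}
true richness:     {'R1': 11, 'R2': 17, 'R3': 12}
region  n_observed  median  q2.5  q97.5
    R1          11      12    11     40
    R2          17      18    17     40
    R3          11      12    11     40
 quantity  mean  q2.5  q97.5
occupancy 0.367 0.136  0.527
detection 0.171 0.141  0.198
```

The richness medians sit one species above the observed counts and the
credible intervals cover the true values; the upper bounds reach the
augmentation cap because a survey this small cannot rule out many
undetected rare species. The meta-community summaries recover the
generating values (occupancy 0.35, per-day detection 0.15) within
their intervals. `co.effect_summary(draws)` adds the covariate table —
with this seed the positive mass and settlement-distance effects on
occupancy and the negative river-distance effect are all flagged as
significant (95% interval excluding zero), matching the generator:

```
        quantity  mean  q2.5  q97.5  excludes_zero
      alpha_mass -0.26 -0.46  -0.05           True
 mu_alpha_dSettl  0.07 -0.12   0.28          False
       beta_mass  0.78  0.11   2.29           True
    mu_beta_dRiv -0.32 -0.60  -0.08           True
  mu_beta_dSettl  0.37  0.05   0.76           True
mu_beta_forCover -0.29 -0.57  -0.02           True
```

## Command line

The same pipeline is scriptable end to end:

```sh
commocc simulate  --seed 1 --out data/          # synthetic survey (CSV + truth)
commocc validate  --data data/                  # dimensions + collinearity screen
commocc fit       --data data/ --out fit/ --chains 3 --iters 50000 \
                  --burnin 5000 --thin 10 --seed 1
commocc diagnose  --draws fit/draws.csv         # Gelman-Rubin Rhat
commocc summarize --draws fit/draws.csv --out tables/
commocc show-config                             # every resolved default
```

`fit` writes a flat draw store (`chain,iter,parameter,value`) that
round-trips bit-exactly; `summarize` turns it into richness,
community-probability, covariate-effect and per-species divergence
tables.

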