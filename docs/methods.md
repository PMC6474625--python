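# Methods

## The model

`commocc` fits a multi-region, multi-species occupancy model to
camera-trap detection data. The data are detection counts
`y[k, i, r]`: the number of daily occasions on which species `k` was
photographed at site `i` of region `r`, out of `effort[i]` trap-days.
Three coupled processes define the joint model per region:

**Community membership with data augmentation.** Each region's species
list is padded to a fixed pool of `M` slots with all-zero detection
histories. A membership indicator

    w_kr ~ Bernoulli(Omega_r)

says whether slot `k` is a real member of region `r`'s community; for
detected species `w` is fixed at 1. Regional richness is
`N_r = sum_k w_kr`, with `E[N_r] = M * Omega_r`, so `Omega_r` and
`N_r` are equivalent parameters. `M` must comfortably exceed the
largest observed richness (the production default is `M = 100`, about
three times the largest observed species count in the survey this
package is modelled on).

**Occupancy.** Conditional on membership,

    z_kir | w_kr ~ Bernoulli(w_kr * psi_kir)
    logit(psi_kir) = beta0_kr + beta1 * logmass_kr
                     + beta2_kr * dRiv_ir + beta3_kr * dSettl_ir
                     + beta4_kr * forCover_ir

**Detection.** Conditional on occupancy,

    y_kir | z_kir ~ Binomial(effort_i, z_kir * p_kir)
    logit(p_kir) = alpha0_kr + alpha1 * logmass_kr + alpha2_kr * dSettl_ir

`p` is a per-day detection probability. Setting every effort to 1
recovers the Bernoulli observation model, available as
`ModelConfig(observation="bernoulli")`; the Binomial form is the
default because multi-day deployments carry real information about
`p`.

Intercepts and site-covariate slopes are species-region random effects
with community-level hyperparameters shared across regions
(`beta0_kr ~ Normal(mu_beta0, sigma_beta0^2)` and likewise for each
slope family). The body-mass slopes `beta1`/`alpha1` are
community-level scalars: a species-specific slope on a
species-constant covariate is absorbed by that species' intercept and
is not separately identifiable. A species-region random-effects
reading of the mass slopes is nevertheless available for sensitivity
analysis (`ModelConfig(mass_random_slopes=True)`).

**Body mass.** Log-transformed body mass, standardized over the
detected species of the landscape, is modelled per region as
`logmass_kr ~ Normal(mu_mass_r, sigma_mass_r^2)`. Masses are observed
data for detected species and latent parameters for augmented slots;
the posterior of `mu_mass_r` is the estimated average community body
mass of region `r` on the standardized log scale. The mass model is
applied to all `M` pool slots of a region (the natural vectorized
reading under data augmentation), so `mu_mass_r` describes the pool of
potential members, dominated by the actual community when `Omega` is
well away from saturation.

## Priors

- `Omega_r`, `mu_beta0`, `mu_alpha0`: Normal(0, SD 10) on the logit
  scale. This is the "Normal(0, 0.01)" of BUGS/JAGS notation read in
  the precision parameterization; an SD of 0.1 would pin these
  quantities near 0.5 on the probability scale, which is clearly not
  the weakly-informative intent.
- community-level slopes and slope hyper-means: Uniform(-10, 10);
- all random-effect SDs: Uniform(0, 10);
- `mu_mass_r`: Normal(0, SD 10); `sigma_mass_r`: Uniform(0, 10).

Every prior constant is a field of `PriorSpec` and is printed by
`commocc show-config` so the parameterization is auditable.

## Sampler

A Metropolis-within-Gibbs kernel (`commocc.mcmc.GibbsKernel`) updates,
per sweep:

1. `w` for augmented slots from its exact conditional with the site
   states marginalized: `P(w=1) = expit(logit(Omega) + log L1)` with
   `L1 = prod_i [psi (1-p)^effort + 1 - psi]`; then `z | w` from its
   exact conditional (detections force `z = 1`). Drawing `w` with `z`
   collapsed and then `z | w` is a valid joint block update and avoids
   the sticking that plagues naive one-at-a-time updates of (w, z).
2. `Omega_r` by random-walk Metropolis on the logit scale.
3. Species-region coefficients by *elementwise* random-walk Metropolis
   against their Bernoulli (occupancy) or Binomial (detection)
   likelihoods. Slots whose likelihood is vacuous (non-members for the
   occupancy side; slots with no occupied site for the detection side)
   are refreshed by an exact draw from their hyperdistribution, which
   is their full conditional.
4. The community mass slopes by scalar random-walk Metropolis.
5. Latent log-masses of augmented slots by elementwise Metropolis
   (members) or an exact draw from the region mass model (non-members).
6. Per coefficient family, two joint hyper moves: a *translate* move
   proposing a common shift of the hyper-mean and every random effect,
   and a *rescale* move proposing a common scaling of the hyper-SD and
   every deviation (acceptance ratio `delta-loglik + eps`, the prior
   and Jacobian terms cancelling up to one scale factor). These moves
   break the strong posterior coupling between hyperparameters and
   their weakly-informed random effects; without them the
   hierarchical SDs dominate the integrated autocorrelation time.
7. Hyper-means by conjugate Normal draws (truncated to the Uniform
   support for slope hyper-means) and hyper-SDs by exact inverse-gamma
   draws truncated to their Uniform support, batched through
   `gammaincc`/`gammainccinv` rather than generic distribution objects
   for speed.

Proposal scales adapt by Robbins-Monro (step `min(0.25, 2/sqrt(t+20))`
toward acceptance 0.44) during burn-in only and are frozen afterwards,
so every retained draw comes from a fixed, detailed-balanced kernel.
Each chain's RNG stream is spawned from the master seed via
`numpy.random.SeedSequence`, making runs bit-reproducible and chains
independent of how many are run.

The production schedule (3 chains x 50,000 iterations, burn-in 5,000,
thin 10) retains 13,500 draws. Regions with different site counts are
padded to a common width with `effort = 0` and a site mask; padded
columns contribute nothing to any likelihood.

### Validation

The test suite checks the kernel three independent ways:

- the discrete-latent conditionals against exhaustive enumeration of
  the joint posterior on all small instances (tolerance 1e-12);
- simulation-based calibration (SBC): 200 prior-predictive replicates
  at reduced scale (2 regions, 10 sites, pool 15, effort 5) are each
  fit with a 2,000-iteration chain; the ranks of the true `mu_beta0`,
  `mu_alpha0`, `beta1` and `Omega_1` among 100 retained draws must be
  uniform (chi-squared, alpha = 0.01). SBC is run with a narrower
  proper prior (logit-scale SDs of 1, slopes Uniform(-2, 2), SDs
  Uniform(0.05, 1)) than the production prior: SBC validates the
  sampler for whichever proper prior is used, and the production
  prior's SD-10 logit scales make almost every prior-predictive
  dataset degenerate (all-zero or saturated) at this scale, testing
  nothing. With short chains the detection-side intercept shows mild
  rank skew from residual autocorrelation; with long well-thinned
  chains (6,000 iterations, thin 50) the rank histograms are flat,
  confirming the skew is a chain-length artifact rather than bias.
- parameter recovery at survey-like scale (3 regions x 40 sites,
  effort 20, pool 30, fitted with M = 40), generating with the
  community slope values the model is designed to estimate
  (`beta1 = 0.76`, `beta2 = -0.20`, `beta3 = 0.23`, `alpha2 = 0.17`):
  posterior means must land within 2 posterior SDs of truth, and true
  `N_r` must fall in the 95% credible interval in at least 90% of 50
  replicates. The recovery intercepts (`mu_beta0 = -0.85`,
  `mu_alpha0 = -2.5`) were chosen so that a realistic fraction of
  community members escapes detection, making richness estimation a
  non-trivial task.

## Synthetic data generator

`commocc.simulate` draws datasets from the model's own generative
process. The study-structure preset mirrors the survey the package is
modelled on: 5 regions with {51, 34, 26, 25, 28} sites (164 total),
integer effort uniform on 12-49 trap-days, community mean occupancy
0.26 and per-day detection 0.04 on the probability scale, slope
hyper-means at the estimates reported for that system, and slope
hyper-SDs of 0.25 (a moderate degree of among-species variation,
chosen once; the survey reported no hyper-SD estimates). Body masses
are log-normal (median ~12 kg, log-SD 1.8), spanning mongoose-sized to
elephant-sized species.

Site covariates are multivariate normal with the survey's correlation
structure: distance to settlements vs distance to the protected-area
boundary at Pearson r = 0.65, and moist-forest cover vs lumped open
habitats at r = -0.82 — the two collinear companions are generated so
that the screening step (`correlation_screen`, threshold |r| >= 0.7)
has something to flag, exactly as the field workflow dropped them.
Distances are lightly clipped at 1 m and cover fractions to [0, 1].

One generator feature goes beyond the fitted model: a species-level
membership random effect (`species_range_sd`) induces wide-ranging
species that occur in every region, reproducing the observed pattern
of a landscape pool (~48 species) with a ubiquitous core (~13
species). The fitted model assumes memberships are independent given
`Omega_r`; the reduced and recovery presets therefore set
`species_range_sd = 0` so generator and model agree exactly, and the
study preset uses it only to make structural dimensions realistic.

What the generator does *not* emulate: spatial autocorrelation among
sites, animal movement and home-range overlap (detections at nearby
cameras are independent given `z`), temporal variation within a
season, and misidentification. Passing recovery tests therefore shows
the estimator works when the model is true at realistic dimensions —
not that these field complications are harmless.

## Posterior summaries

All credible intervals are central 95% percentile intervals of the
retained draws. Richness summaries use nearest-observation quantiles
so they remain integers and can never fall below the observed count.
"Meta-community occupancy/detection" is the posterior of the
inverse-logit of the community hyper-mean intercept, i.e. the
probability for a typical species at a site with covariates at their
standardized mean; detection is per trap-day. An effect is
"significant" when its 95% interval excludes zero; the summary also
reports the posterior probability of the effect's sign. A species is
flagged as diverging from the community when its 95% interval and the
hyper-mean's 95% interval are disjoint.

`gelman_rubin` implements the classic between/within-chain potential
scale reduction factor, floored at 1.0 (the raw estimator falls
slightly below 1 when the between-chain variance is nil, as on
duplicated chains).

## Numerical choices and degenerate inputs

- Probabilities are clipped at 1e-12 from the boundaries inside the
  kernel; likelihood evaluations use `log1p`/`logaddexp` throughout.
- `y > 0` with `z = 0` yields a log-likelihood of -inf (an impossible
  state), not an exception.
- Zero-variance covariates, empty detection tables, augmentation pools
  not exceeding the largest observed richness, and non-positive-definite
  covariate correlation targets are rejected with explicit errors.
- A model with zero sites is valid and samples its prior (used as a
  sampler check).
- Draw stores round-trip bit-exactly: values are written with
  shortest-round-trip reprs and parsed with pandas'
  `float_precision="round_trip"`.

## Problem sizes used by the checked artifacts

The test suite fits the reduced preset (3 regions x 20 sites, pool 25,
M = 40) with 2 chains x 9,000 iterations, runs SBC at 2 x 10 sites
with 200 replicates x 2,000 iterations, and runs 50 recovery
replicates at 3 x 40 sites with 1,200-iteration chains. The
acceptance script fits the full study structure (5 regions, 164
sites, M = 100) with 3 chains x 4,000 iterations, thinned to 1,500
retained draws. These schedules were verified against the Gelman-Rubin
diagnostic (all monitored Rhat <= 1.1 on the reduced fit); production
analyses should use the full 3 x 50,000 schedule.

## Known limitations

- Single-season model: no colonization/extinction dynamics.
- No spatial random effects; sites are exchangeable given covariates.
- The Uniform(0, M) prior on `N_r` induced by a flat `Omega` is
  implemented through the logit-Normal prior on `Omega_r` (SD 10),
  which is flat in the relevant range but not exactly uniform.
- The optional Pólya-Gamma conjugate coefficient updates often paired
  with logit models are not implemented; the adaptive random-walk
  kernel with joint hyper moves met every calibration and runtime
  requirement without an extra dependency.
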