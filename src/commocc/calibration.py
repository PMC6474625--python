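"""Simulation-based calibration (SBC) for the Gibbs sampler.

SBC validates a sampler end-to-end: draw hyperparameters from the
prior, simulate a dataset from them, fit the model to that dataset,
and record the rank of each true hyperparameter among the retained
posterior draws. If the sampler targets the correct posterior, these
ranks are uniform over replicates; a chi-squared goodness-of-fit test
against uniformity flags systematic bias or over/under-dispersion.

The harness draws datasets directly on the model's own scale (the
observed log-masses enter as data without re-standardization, and the
augmented pool size equals the generating pool size so the membership
probability Omega retains its meaning), which is exactly the
correspondence SBC requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chisquare

from .mcmc import McmcConfig, run_chains
from .model import ModelConfig, ModelData, PriorSpec

__all__ = ["SbcDims", "draw_prior_dataset", "run_sbc", "rank_uniformity_pvalues"]

#: hyperparameters whose ranks the calibration tracks by default
DEFAULT_PARAMS = ("mu_beta0", "mu_alpha0", "beta_mass", "Omega[R1]")


@dataclass
class SbcDims:
    """Problem size of one calibration replicate."""

    R: int = 2
    S: int = 10
    M: int = 15
    effort: int = 5
    n_psi_cov: int = 0
    n_p_cov: int = 0


def draw_prior_dataset(
    priors: PriorSpec, dims: SbcDims, rng: np.random.Generator
) -> tuple[dict, ModelData]:
    """One draw from the prior predictive: true hypers + dataset.

    Detected slots are moved to the front of each region's pool (the
    layout the model expects); the permutation does not touch the
    hyperparameters being calibrated.
    """
    R, S, M = dims.R, dims.S, dims.M
    truth: dict[str, float] = {}

    omega = expit(rng.normal(priors.omega_logit_mean, priors.omega_logit_sd, size=R))
    mu_b0 = rng.normal(priors.hypermean_mean, priors.hypermean_sd)
    mu_a0 = rng.normal(priors.hypermean_mean, priors.hypermean_sd)
    sig_b0 = rng.uniform(0.05, priors.sd_upper)
    sig_a0 = rng.uniform(0.05, priors.sd_upper)
    beta1 = rng.uniform(priors.slope_lo, priors.slope_hi)
    alpha1 = rng.uniform(priors.slope_lo, priors.slope_hi)
    mu_mass = rng.normal(0.0, priors.mass_mean_sd, size=R)
    sigma_mass = rng.uniform(0.05, priors.mass_sd_upper, size=R)

    psi_names = tuple(f"x{i + 1}" for i in range(dims.n_psi_cov))
    p_names = tuple(f"u{i + 1}" for i in range(dims.n_p_cov))
    mu_psi = rng.uniform(priors.slope_lo, priors.slope_hi, size=dims.n_psi_cov)
    sig_psi = rng.uniform(0.05, priors.sd_upper, size=dims.n_psi_cov)
    mu_p = rng.uniform(priors.slope_lo, priors.slope_hi, size=dims.n_p_cov)
    sig_p = rng.uniform(0.05, priors.sd_upper, size=dims.n_p_cov)

    x_psi = rng.standard_normal((R, S, dims.n_psi_cov))
    x_p = rng.standard_normal((R, S, dims.n_p_cov))

    beta0 = rng.normal(mu_b0, sig_b0, size=(R, M))
    alpha0 = rng.normal(mu_a0, sig_a0, size=(R, M))
    psi_slopes = mu_psi + sig_psi * rng.standard_normal((R, M, dims.n_psi_cov))
    p_slopes = mu_p + sig_p * rng.standard_normal((R, M, dims.n_p_cov))
    logmass = mu_mass[:, None] + sigma_mass[:, None] * rng.standard_normal((R, M))

    eta_psi = (beta0 + beta1 * logmass)[:, :, None] + np.einsum(
        "rkc,rsc->rks", psi_slopes, x_psi
    )
    eta_p = (alpha0 + alpha1 * logmass)[:, :, None] + np.einsum(
        "rkc,rsc->rks", p_slopes, x_p
    )
    w = (rng.random((R, M)) < omega[:, None]).astype(int)
    z = (rng.random((R, M, S)) < w[:, :, None] * expit(eta_psi)).astype(int)
    y = rng.binomial(dims.effort, z * expit(eta_p))

    # detected slots first, per region
    order = np.argsort(~(y.sum(axis=2) > 0), axis=1, kind="stable")
    y = np.take_along_axis(y, order[:, :, None], axis=1)
    logmass_perm = np.take_along_axis(logmass, order, axis=1)
    detected = y.sum(axis=2) > 0
    logmass_obs = np.where(detected, logmass_perm, np.nan)

    truth.update(
        {
            "mu_beta0": float(mu_b0),
            "mu_alpha0": float(mu_a0),
            "sigma_beta0": float(sig_b0),
            "sigma_alpha0": float(sig_a0),
            "beta_mass": float(beta1),
            "alpha_mass": float(alpha1),
        }
    )
    for r in range(R):
        truth[f"Omega[R{r + 1}]"] = float(omega[r])
        truth[f"N[R{r + 1}]"] = float(w[r].sum())
        truth[f"mu_mass[R{r + 1}]"] = float(mu_mass[r])
    for c, nm in enumerate(psi_names):
        truth[f"mu_beta_{nm}"] = float(mu_psi[c])
    for c, nm in enumerate(p_names):
        truth[f"mu_alpha_{nm}"] = float(mu_p[c])

    regions = [f"R{r + 1}" for r in range(R)]
    data = ModelData(
        regions=regions,
        species_by_region={
            rg: [f"sp{k + 1}" for k in range(int(detected[r].sum()))]
            for r, rg in enumerate(regions)
        },
        M=M,
        y=y,
        effort=np.full((R, S), dims.effort, dtype=int),
        site_mask=np.ones((R, S), dtype=bool),
        observed=detected,
        x_psi=x_psi,
        x_p=x_p,
        logmass_obs=logmass_obs,
        config=ModelConfig(
            psi_covariates=psi_names, p_covariates=p_names, use_mass=True
        ),
    )
    return truth, data


def run_sbc(
    priors: PriorSpec,
    dims: SbcDims,
    mcmc: McmcConfig,
    n_replicates: int,
    seed: int,
    params: tuple[str, ...] = DEFAULT_PARAMS,
) -> np.ndarray:
    """Rank statistics over replicates: array (n_replicates, n_params).

    The rank of a true value among L retained draws lies in 0..L and
    is uniform under a correct sampler.
    """
    root = np.random.SeedSequence(seed)
    ranks = np.zeros((n_replicates, len(params)), dtype=int)
    for i, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        truth, data = draw_prior_dataset(priors, dims, rng)
        cfg = McmcConfig(
            n_iter=mcmc.n_iter,
            burn_in=mcmc.burn_in,
            thin=mcmc.thin,
            n_chains=mcmc.n_chains,
            proposal_scales=dict(mcmc.proposal_scales),
            adapt=mcmc.adapt,
            seed=int(rng.integers(2**31 - 1)),
        )
        draws = run_chains(data, priors, cfg)
        for j, par in enumerate(params):
            ranks[i, j] = int((draws.flat(par) < truth[par]).sum())
    return ranks


def rank_uniformity_pvalues(
    ranks: np.ndarray, n_draws: int, n_bins: int = 10
) -> np.ndarray:
    """Chi-squared goodness-of-fit p-value per tracked parameter."""
    ranks = np.asarray(ranks)
    edges = np.linspace(0, n_draws + 1, n_bins + 1)
    pvals = []
    for j in range(ranks.shape[1]):
        counts, _ = np.histogram(ranks[:, j], bins=edges)
        pvals.append(chisquare(counts).pvalue)
    return np.asarray(pvals)
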