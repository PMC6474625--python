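"""Joint probability model for the multi-region community occupancy model.

The model couples three processes per region ``r``:

* community membership:  ``w_kr ~ Bernoulli(Omega_r)`` over an augmented
  pool of ``M`` species slots (fixed to 1 for detected species), so the
  regional richness is ``N_r = sum_k w_kr``;
* occupancy:  ``z_kir | w_kr ~ Bernoulli(w_kr * psi_kir)`` with
  ``logit(psi_kir) = beta0_kr + beta1 * logmass_kr + sum_c beta_c,kr x_c,ir``;
* detection:  ``y_kir | z_kir ~ Binomial(effort_i, z_kir * p_kir)`` with
  ``logit(p_kir) = alpha0_kr + alpha1 * logmass_kr + sum_c alpha_c,kr x_c,ir``,
  where effort is the number of daily occasions a camera operated.
  Setting every effort to 1 recovers the Bernoulli observation model.

Intercepts and site-covariate slopes are species-region random effects
drawn from community-level Normal hyperdistributions whose mean and SD
are shared across regions; the body-mass slopes ``beta1``/``alpha1``
are community-level scalars (a species-specific slope on a
species-constant covariate is absorbed by the intercept and is not
separately identifiable). Log body mass itself is modelled as
``logmass_kr ~ Normal(mu_mass_r, sigma_mass_r^2)`` — observed for
detected species, latent for augmented slots — which yields a posterior
for the average community body mass of each region.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln, logit

from .domain import (
    AugmentedCommunity,
    SpeciesRecord,
    Site,
    standardize_covariates,
)

__all__ = [
    "PriorSpec",
    "ModelConfig",
    "ModelData",
    "ParamState",
    "prepare_model_data",
    "occupancy_prob",
    "detection_prob",
    "loglik",
    "conditional_z",
    "conditional_w",
    "log_prior",
    "log_posterior",
]

_LOG_EPS = 1e-300


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    The logit-scale Normal priors use the *SD* parameterization; the
    weakly-informative default SD of 10 corresponds to a precision of
    0.01 in BUGS/JAGS notation. Random-effect SDs get Uniform(0, upper)
    priors; community-level slopes and slope hyper-means get
    Uniform(lo, hi).
    """

    omega_logit_mean: float = 0.0
    omega_logit_sd: float = 10.0
    hypermean_mean: float = 0.0
    hypermean_sd: float = 10.0
    slope_lo: float = -10.0
    slope_hi: float = 10.0
    sd_upper: float = 10.0
    mass_mean_sd: float = 10.0
    mass_sd_upper: float = 10.0

    def __post_init__(self) -> None:
        if self.omega_logit_sd <= 0 or self.hypermean_sd <= 0 or self.mass_mean_sd <= 0:
            raise ValueError("prior scales must be > 0")
        if not (self.slope_lo < self.slope_hi):
            raise ValueError("slope prior requires lo < hi")
        if self.sd_upper <= 0 or self.mass_sd_upper <= 0:
            raise ValueError("SD prior upper bounds must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


@dataclass
class ModelConfig:
    """Structural switches for the fitted model."""

    psi_covariates: tuple[str, ...] = ("dRiv", "dSettl", "forCover")
    p_covariates: tuple[str, ...] = ("dSettl",)
    observation: str = "binomial"  # or "bernoulli" (collapse counts to 0/1)
    use_mass: bool = True
    mass_random_slopes: bool = False  # species-region beta1/alpha1 (sensitivity)

    def __post_init__(self) -> None:
        if self.observation not in ("binomial", "bernoulli"):
            raise ValueError("observation must be 'binomial' or 'bernoulli'")
        self.psi_covariates = tuple(self.psi_covariates)
        self.p_covariates = tuple(self.p_covariates)


@dataclass
class ModelData:
    """Dense padded arrays the likelihood and sampler operate on.

    Regions are padded to a common site count ``S``; padded site
    columns have ``effort = 0`` and ``site_mask`` false so they never
    contribute to any likelihood sum.
    """

    regions: list[str]
    species_by_region: dict[str, list[str]]
    M: int
    y: np.ndarray  # int (R, M, S)
    effort: np.ndarray  # int (R, S)
    site_mask: np.ndarray  # bool (R, S)
    observed: np.ndarray  # bool (R, M)
    x_psi: np.ndarray  # float (R, S, C_psi)
    x_p: np.ndarray  # float (R, S, C_p)
    logmass_obs: np.ndarray  # float (R, M), nan on augmented slots
    config: ModelConfig
    mass_center: float = 0.0
    mass_scale: float = 1.0

    @property
    def R(self) -> int:
        return len(self.regions)

    @property
    def S(self) -> int:
        return self.y.shape[2]

    @property
    def n_obs(self) -> np.ndarray:
        return self.observed.sum(axis=1)


@dataclass
class ParamState:
    """One full assignment of all unknowns in the model."""

    omega: np.ndarray  # (R,)
    mu_beta0: float
    sigma_beta0: float
    mu_alpha0: float
    sigma_alpha0: float
    beta1: float
    alpha1: float
    mu_psi_slopes: np.ndarray  # (C_psi,)
    sigma_psi_slopes: np.ndarray  # (C_psi,)
    mu_p_slopes: np.ndarray  # (C_p,)
    sigma_p_slopes: np.ndarray  # (C_p,)
    beta0: np.ndarray  # (R, M)
    psi_slopes: np.ndarray  # (R, M, C_psi)
    alpha0: np.ndarray  # (R, M)
    p_slopes: np.ndarray  # (R, M, C_p)
    mu_mass: np.ndarray  # (R,)
    sigma_mass: np.ndarray  # (R,)
    logmass: np.ndarray  # (R, M)
    w: np.ndarray  # int (R, M)
    z: np.ndarray  # int (R, M, S)
    # species-region deviations of the mass slopes, used only when
    # ModelConfig.mass_random_slopes is on (otherwise identically zero)
    beta1_dev: np.ndarray | None = None  # (R, M)
    alpha1_dev: np.ndarray | None = None  # (R, M)
    sigma_beta1: float = 1.0
    sigma_alpha1: float = 1.0

    @property
    def beta1_full(self):
        """Effective mass slope on occupancy, scalar or (R, M)."""
        return self.beta1 if self.beta1_dev is None else self.beta1 + self.beta1_dev

    @property
    def alpha1_full(self):
        return self.alpha1 if self.alpha1_dev is None else self.alpha1 + self.alpha1_dev

    def copy(self) -> "ParamState":
        return ParamState(
            omega=self.omega.copy(),
            mu_beta0=self.mu_beta0,
            sigma_beta0=self.sigma_beta0,
            mu_alpha0=self.mu_alpha0,
            sigma_alpha0=self.sigma_alpha0,
            beta1=self.beta1,
            alpha1=self.alpha1,
            mu_psi_slopes=self.mu_psi_slopes.copy(),
            sigma_psi_slopes=self.sigma_psi_slopes.copy(),
            mu_p_slopes=self.mu_p_slopes.copy(),
            sigma_p_slopes=self.sigma_p_slopes.copy(),
            beta0=self.beta0.copy(),
            psi_slopes=self.psi_slopes.copy(),
            alpha0=self.alpha0.copy(),
            p_slopes=self.p_slopes.copy(),
            mu_mass=self.mu_mass.copy(),
            sigma_mass=self.sigma_mass.copy(),
            logmass=self.logmass.copy(),
            w=self.w.copy(),
            z=self.z.copy(),
            beta1_dev=None if self.beta1_dev is None else self.beta1_dev.copy(),
            alpha1_dev=None if self.alpha1_dev is None else self.alpha1_dev.copy(),
            sigma_beta1=self.sigma_beta1,
            sigma_alpha1=self.sigma_alpha1,
        )


def prepare_model_data(
    aug: AugmentedCommunity,
    traits: Sequence[SpeciesRecord],
    config: ModelConfig | None = None,
) -> ModelData:
    """Assemble padded arrays from augmented detection data and traits.

    Body masses are log-transformed and standardized (mean 0, SD 1,
    population convention) over the distinct detected species of the
    landscape; augmented slots get NaN and are treated as latent.
    """
    config = config or ModelConfig()
    det = aug.detection
    regions = det.regions
    R, M = len(regions), aug.M
    S = max(len(det.sites_by_region[r]) for r in regions)

    mass_by_species = {t.species_id: t.mass_kg for t in traits}
    observed_species = det.all_species
    missing = [sp for sp in observed_species if sp not in mass_by_species]
    if config.use_mass and missing:
        raise ValueError(f"species missing from trait table: {missing}")
    if config.use_mass:
        lm = np.log([mass_by_species[sp] for sp in observed_species])
        center, scale = float(lm.mean()), float(lm.std(ddof=0))
        if scale == 0.0:
            scale = 1.0
        lm_std = {sp: (v - center) / scale for sp, v in zip(observed_species, lm)}
    else:
        center, scale = 0.0, 1.0
        lm_std = {sp: 0.0 for sp in observed_species}

    y = np.zeros((R, M, S), dtype=int)
    effort = np.zeros((R, S), dtype=int)
    site_mask = np.zeros((R, S), dtype=bool)
    logmass_obs = np.full((R, M), np.nan)
    all_sites: list[Site] = []
    for r in regions:
        all_sites.extend(det.sites_by_region[r])
    n_psi, n_p = len(config.psi_covariates), len(config.p_covariates)
    x_psi = np.zeros((R, S, n_psi))
    x_p = np.zeros((R, S, n_p))
    needed = tuple(dict.fromkeys(config.psi_covariates + config.p_covariates))
    if needed:
        design, _spec = standardize_covariates(all_sites, needed)
        col = {name: j for j, name in enumerate(needed)}
    for ri, r in enumerate(regions):
        sites = det.sites_by_region[r]
        s_r = len(sites)
        site_mask[ri, :s_r] = True
        effort[ri, :s_r] = [s.effort for s in sites]
        y[ri, : det.n_species(r), :s_r] = det.y[r]
        for k, sp in enumerate(det.species_by_region[r]):
            logmass_obs[ri, k] = lm_std[sp]
        if needed:
            for j, name in enumerate(config.psi_covariates):
                x_psi[ri, :s_r, j] = design[r][:, col[name]]
            for j, name in enumerate(config.p_covariates):
                x_p[ri, :s_r, j] = design[r][:, col[name]]

    if config.observation == "bernoulli":
        y = np.minimum(y, 1)
        effort = np.where(site_mask, np.minimum(effort, 1), 0)

    return ModelData(
        regions=list(regions),
        species_by_region={r: list(det.species_by_region[r]) for r in regions},
        M=M,
        y=y,
        effort=effort,
        site_mask=site_mask,
        observed=aug.observed_mask.copy(),
        x_psi=x_psi,
        x_p=x_p,
        logmass_obs=logmass_obs,
        config=config,
        mass_center=center,
        mass_scale=scale,
    )


def _linear_predictor(
    intercept: np.ndarray,
    mass_coef,
    logmass: np.ndarray,
    slopes: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    eta = (intercept + np.asarray(mass_coef) * logmass)[:, :, None]
    if x.shape[2]:
        eta = eta + np.einsum("rkc,rsc->rks", slopes, x)
    else:
        eta = np.broadcast_to(eta, eta.shape[:2] + (x.shape[1],)).copy()
    return eta


def occupancy_prob(state: ParamState, data: ModelData) -> np.ndarray:
    """psi[r, k, i] from the logit-linear occupancy regression."""
    eta = _linear_predictor(
        state.beta0, state.beta1_full, state.logmass, state.psi_slopes, data.x_psi
    )
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite occupancy linear predictor")
    return expit(eta)


def detection_prob(state: ParamState, data: ModelData) -> np.ndarray:
    """p[r, k, i] from the logit-linear detection regression."""
    eta = _linear_predictor(
        state.alpha0, state.alpha1_full, state.logmass, state.p_slopes, data.x_p
    )
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite detection linear predictor")
    return expit(eta)


def loglik(
    y: np.ndarray,
    effort: np.ndarray,
    z: np.ndarray,
    p: np.ndarray,
    site_mask: np.ndarray | None = None,
) -> float:
    """Binomial observation log-likelihood given the occupancy states.

    ``y`` and ``z`` have shape (..., sites); ``effort`` broadcasts over
    the species axis. Cells with ``z = 0`` contribute 0 when ``y = 0``
    and -inf when ``y > 0`` (an inconsistent state, reported as a
    degenerate likelihood rather than an exception).
    """
    y = np.asarray(y)
    z = np.asarray(z)
    p = np.asarray(p, dtype=float)
    eff = np.broadcast_to(np.asarray(effort), y.shape)
    if site_mask is not None:
        keep = np.broadcast_to(site_mask, y.shape)
    else:
        keep = np.ones(y.shape, dtype=bool)

    if np.any((y > 0) & (z == 0) & keep):
        return float("-inf")

    occ = (z == 1) & keep
    yo = y[occ]
    no = eff[occ]
    po = np.clip(p[occ], _LOG_EPS, 1 - 1e-16)
    terms = (
        gammaln(no + 1)
        - gammaln(yo + 1)
        - gammaln(no - yo + 1)
        + yo * np.log(po)
        + (no - yo) * np.log1p(-po)
    )
    return float(terms.sum())


def conditional_z(
    y: np.ndarray,
    effort: np.ndarray,
    psi: np.ndarray,
    p: np.ndarray,
    w: np.ndarray,
) -> np.ndarray:
    """Full-conditional P(z = 1) per cell.

    A detection anywhere in the cell forces z = 1; for an all-zero cell
    of a community member, P(z=1) = psi (1-p)^effort /
    (psi (1-p)^effort + 1 - psi). Non-members (w = 0) have z = 0.
    """
    y = np.asarray(y)
    psi = np.asarray(psi, dtype=float)
    p = np.asarray(p, dtype=float)
    shape = np.broadcast_shapes(y.shape, psi.shape, p.shape)
    eff = np.broadcast_to(np.asarray(effort), shape)
    w_arr = np.asarray(w)
    if w_arr.ndim == len(shape) - 1:
        w_arr = w_arr[..., None]
    w_b = np.broadcast_to(w_arr, shape)

    miss = np.exp(eff * np.log1p(-np.clip(p, 0.0, 1 - 1e-16)))
    num = psi * miss
    den = num + (1.0 - psi)
    with np.errstate(invalid="ignore"):
        prob = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    prob = np.where(np.broadcast_to(y, shape) > 0, 1.0, prob)
    return prob * w_b


def conditional_w(
    y_slot: np.ndarray,
    effort: np.ndarray,
    psi_slot: np.ndarray,
    p_slot: np.ndarray,
    omega: float,
) -> float:
    """Full-conditional P(w = 1) for an augmented (all-zero) slot.

    Marginalizes the site occupancy states: the likelihood of an
    all-zero history for a present species is
    ``L1 = prod_i [psi_i (1-p_i)^effort_i + 1 - psi_i]``, giving
    ``P(w=1 | ...) = Omega L1 / (Omega L1 + 1 - Omega)``.
    """
    y_slot = np.asarray(y_slot)
    if np.any(y_slot > 0):
        raise ValueError("conditional_w called on a detected slot (w is fixed at 1)")
    psi_slot = np.asarray(psi_slot, dtype=float)
    p_slot = np.asarray(p_slot, dtype=float)
    eff = np.broadcast_to(np.asarray(effort), psi_slot.shape)
    miss = np.exp(eff * np.log1p(-np.clip(p_slot, 0.0, 1 - 1e-16)))
    log_l1 = float(np.log(psi_slot * miss + (1.0 - psi_slot)).sum())
    if omega <= 0.0:
        return 0.0
    if omega >= 1.0:
        return 1.0
    return float(expit(logit(omega) + log_l1))


def _norm_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def log_prior(state: ParamState, priors: PriorSpec, data: ModelData) -> float:
    """Log-density of everything except the observation model.

    Includes the hyperpriors, the random-effect (coefficient) terms,
    the community-membership and occupancy-state pmfs, and the body
    mass model (both the observed masses, which inform ``mu_mass``,
    and the latent masses of augmented slots), so that
    ``log_posterior = log_prior + loglik`` with no term counted twice.
    The Omega prior is evaluated on the logit scale, the coordinate in
    which it is specified and sampled.
    """
    total = 0.0
    # hyperpriors
    lo_om = logit(np.clip(state.omega, 1e-15, 1 - 1e-15))
    total += float(
        _norm_logpdf(lo_om, priors.omega_logit_mean, priors.omega_logit_sd).sum()
    )
    total += float(_norm_logpdf(state.mu_beta0, priors.hypermean_mean, priors.hypermean_sd))
    total += float(_norm_logpdf(state.mu_alpha0, priors.hypermean_mean, priors.hypermean_sd))
    width = priors.slope_hi - priors.slope_lo
    for v in (
        state.beta1,
        state.alpha1,
        *np.atleast_1d(state.mu_psi_slopes),
        *np.atleast_1d(state.mu_p_slopes),
    ):
        if not (priors.slope_lo <= v <= priors.slope_hi):
            return float("-inf")
        total += -np.log(width)
    for s in (
        state.sigma_beta0,
        state.sigma_alpha0,
        *np.atleast_1d(state.sigma_psi_slopes),
        *np.atleast_1d(state.sigma_p_slopes),
    ):
        if not (0.0 < s <= priors.sd_upper):
            return float("-inf")
        total += -np.log(priors.sd_upper)
    if np.any(state.sigma_mass <= 0) or np.any(state.sigma_mass > priors.mass_sd_upper):
        return float("-inf")
    total += -len(state.sigma_mass) * np.log(priors.mass_sd_upper)
    total += float(_norm_logpdf(state.mu_mass, 0.0, priors.mass_mean_sd).sum())

    # random effects given hypers
    total += float(_norm_logpdf(state.beta0, state.mu_beta0, state.sigma_beta0).sum())
    total += float(_norm_logpdf(state.alpha0, state.mu_alpha0, state.sigma_alpha0).sum())
    for c in range(state.psi_slopes.shape[2]):
        total += float(
            _norm_logpdf(
                state.psi_slopes[:, :, c],
                state.mu_psi_slopes[c],
                state.sigma_psi_slopes[c],
            ).sum()
        )
    for c in range(state.p_slopes.shape[2]):
        total += float(
            _norm_logpdf(
                state.p_slopes[:, :, c], state.mu_p_slopes[c], state.sigma_p_slopes[c]
            ).sum()
        )

    if data.config.mass_random_slopes:
        for dev, s in (
            (state.beta1_dev, state.sigma_beta1),
            (state.alpha1_dev, state.sigma_alpha1),
        ):
            if dev is None:
                raise ValueError("mass_random_slopes requires deviation arrays")
            if not (0.0 < s <= priors.sd_upper):
                return float("-inf")
            total += -np.log(priors.sd_upper)
            total += float(_norm_logpdf(dev, 0.0, s).sum())

    # body-mass model over every pool slot (observed masses are data
    # informing mu_mass; latent masses are parameters)
    total += float(
        _norm_logpdf(
            state.logmass, state.mu_mass[:, None], state.sigma_mass[:, None]
        ).sum()
    )

    # community membership and occupancy states
    om = state.omega[:, None]
    w = state.w
    total += float((w * np.log(np.clip(om, _LOG_EPS, 1)) +
                    (1 - w) * np.log(np.clip(1 - om, _LOG_EPS, 1))).sum())
    psi = occupancy_prob(state, data)
    wz_prob = w[:, :, None] * psi
    z = state.z
    keep = data.site_mask[:, None, :]
    if np.any((z == 1) & (w[:, :, None] == 0) & keep):
        return float("-inf")
    pz = np.where(z == 1, wz_prob, 1.0 - wz_prob)
    total += float(np.log(np.clip(pz, _LOG_EPS, 1.0))[np.broadcast_to(keep, z.shape)].sum())
    return total


def log_posterior(state: ParamState, priors: PriorSpec, data: ModelData) -> float:
    lp = log_prior(state, priors, data)
    if not np.isfinite(lp):
        return lp
    p = detection_prob(state, data)
    return lp + loglik(data.y, data.effort[:, None, :], state.z, p, data.site_mask[:, None, :])
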