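"""Synthetic multi-region camera-trap data with known ground truth.

The generator draws from the same hierarchical process the model fits:
community-level hyperparameters fix the distributions of species-region
intercepts and slopes, membership indicators ``w`` select which pool
species belong to each regional community, occupancy states ``z`` are
Bernoulli in the species- and site-specific ``psi``, and detection
counts are Binomial in the per-day detection probability ``p`` over
each site's trap-days.

The default configuration mirrors the structure of the five-area
Tanzanian survey the model was built for: 5 regions with
{51, 34, 26, 25, 28} sites, effort 12-49 trap-days per site, roughly
24-33 detected species per region from a landscape pool in which a
fraction of wide-ranging species occurs everywhere, and site covariates
(distance to settlements, distance to rivers, moist-forest cover, plus
two screening companions) with the observed correlation structure
(dSettl vs distance-to-boundary r = 0.65, moist forest vs lumped open
habitats r = -0.82).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .domain import (
    DetectionData,
    Site,
    SpeciesRecord,
    standardize_covariates,
    write_detections_csv,
    write_sites_csv,
    write_traits_csv,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "study_scale",
    "reduced_scale",
    "generate_covariates",
    "generate_community",
    "generate_detections",
    "generate_dataset",
    "write_dataset",
]

_COV_NAMES = ("dSettl", "dBound", "dRiv", "forCover", "openCover")


def _default_corr() -> np.ndarray:
    c = np.eye(5)
    c[0, 1] = c[1, 0] = 0.65  # settlements vs protected-area boundary
    c[3, 4] = c[4, 3] = -0.82  # moist forest vs lumped open habitats
    return c


@dataclass
class GeneratorConfig:
    """All knobs of the generative process, with study-structure defaults."""

    n_regions: int = 5
    sites_per_region: tuple[int, ...] = (51, 34, 26, 25, 28)
    effort_range: tuple[int, int] = (12, 49)
    pool_size: int = 55  # landscape pool of potential species
    omega: float | tuple[float, ...] = 0.55  # membership probability per region
    species_range_sd: float = 2.2  # species-level spread in membership (0 = iid w)

    # community hyperparameters (logit scale; slopes on standardized covariates)
    mu_beta0: float = -1.045  # logit(0.26): mean community occupancy
    sigma_beta0: float = 1.0
    mu_alpha0: float = -3.178  # logit(0.04): mean per-day detection
    sigma_alpha0: float = 0.75
    beta1: float = 0.76  # log body mass on occupancy
    alpha1: float = -0.14  # log body mass on detection
    mu_beta2: float = -0.20  # distance to rivers on occupancy
    sigma_beta2: float = 0.25
    mu_beta3: float = 0.23  # distance to settlements on occupancy
    sigma_beta3: float = 0.25
    mu_beta4: float = -0.14  # moist-forest cover on occupancy
    sigma_beta4: float = 0.25
    mu_alpha2: float = 0.17  # distance to settlements on detection
    sigma_alpha2: float = 0.25

    # body mass distribution of the pool (kg)
    mass_log_mean: float = 2.5  # ~12 kg median
    mass_log_sd: float = 1.8

    # covariate marginals and correlation structure
    covariate_names: tuple[str, ...] = _COV_NAMES
    covariate_means: tuple[float, ...] = (6000.0, 4000.0, 1500.0, 0.48, 0.42)
    covariate_sds: tuple[float, ...] = (2500.0, 2000.0, 900.0, 0.22, 0.20)
    covariate_corr: np.ndarray = field(default_factory=_default_corr)

    seed: int = 0

    def __post_init__(self) -> None:
        self.sites_per_region = tuple(int(s) for s in self.sites_per_region)
        if len(self.sites_per_region) != self.n_regions:
            raise ValueError("sites_per_region length must equal n_regions")
        if any(s < 2 for s in self.sites_per_region):
            raise ValueError("each region needs at least 2 sites")
        lo, hi = self.effort_range
        if not (1 <= lo <= hi <= 365):
            raise ValueError("effort_range must satisfy 1 <= lo <= hi <= 365")
        om = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if om.size == 1:
            om = np.repeat(om, self.n_regions)
        if om.size != self.n_regions or np.any((om <= 0) | (om >= 1)):
            raise ValueError("omega must lie in (0, 1) per region")
        self.omega_by_region = om
        for s in (
            self.sigma_beta0,
            self.sigma_alpha0,
            self.sigma_beta2,
            self.sigma_beta3,
            self.sigma_beta4,
            self.sigma_alpha2,
            self.mass_log_sd,
        ):
            if s < 0:
                raise ValueError("hyper-SDs must be >= 0")
        self.covariate_corr = np.asarray(self.covariate_corr, dtype=float)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def study_scale(seed: int = 0) -> GeneratorConfig:
    """Configuration emulating the five-area survey's dimensions."""
    return GeneratorConfig(seed=seed)


def reduced_scale(seed: int = 0) -> GeneratorConfig:
    """Small configuration for fast tests: 3 regions, 20 sites each.

    Detection and occupancy intercepts are raised relative to the
    study preset so that short surveys (5-10 trap-days) still detect a
    workable share of the community; membership is iid (no
    species-range effect), matching the fitted model exactly.
    """
    return GeneratorConfig(
        n_regions=3,
        sites_per_region=(20, 20, 20),
        effort_range=(5, 10),
        pool_size=25,
        omega=0.5,
        species_range_sd=0.0,
        mu_beta0=logit(0.35),
        sigma_beta0=0.8,
        mu_alpha0=logit(0.15),
        sigma_alpha0=0.5,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Ground-truth latent states and parameters of one generated dataset."""

    species: list[str]
    mass_kg: np.ndarray  # (P,)
    logmass_std: np.ndarray  # (P,) standardized over the pool
    omega: np.ndarray  # (R,)
    w: np.ndarray  # int (R, P)
    z: np.ndarray  # int (R, P, S_max), padded with zeros
    psi: np.ndarray  # (R, P, S_max)
    p: np.ndarray  # (R, P, S_max)
    site_mask: np.ndarray  # bool (R, S_max)
    beta0: np.ndarray  # (R, P)
    psi_slopes: np.ndarray  # (R, P, 3) for (dRiv, dSettl, forCover)
    alpha0: np.ndarray  # (R, P)
    p_slopes: np.ndarray  # (R, P, 1) for (dSettl,)
    beta1: float
    alpha1: float

    @property
    def n_true(self) -> np.ndarray:
        """True regional richness N_r = sum_k w_kr."""
        return self.w.sum(axis=1)

    def to_json(self) -> str:
        d = {
            "species": self.species,
            "beta1": self.beta1,
            "alpha1": self.alpha1,
            "omega": self.omega.tolist(),
            "n_true": self.n_true.tolist(),
            "mass_kg": self.mass_kg.tolist(),
            "logmass_std": self.logmass_std.tolist(),
            "w": self.w.tolist(),
        }
        return json.dumps(d, indent=1)


def generate_covariates(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[Site]:
    """Draw the site table: regions, effort and correlated covariates.

    Covariates are multivariate normal with the configured marginal
    means/SDs and correlation matrix, lightly clipped to their physical
    support (distances >= 1 m, cover fractions in [0, 1]).
    """
    rng = rng or np.random.default_rng(config.seed)
    n = sum(config.sites_per_region)
    corr = config.covariate_corr
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariate correlation matrix is not positive definite") from exc
    zmat = rng.standard_normal((n, corr.shape[0]))
    vals = zmat @ L.T
    vals = np.asarray(config.covariate_means) + vals * np.asarray(config.covariate_sds)
    for j, name in enumerate(config.covariate_names):
        if name.startswith("d"):
            vals[:, j] = np.maximum(vals[:, j], 1.0)
        else:
            vals[:, j] = np.clip(vals[:, j], 0.0, 1.0)
    effort = rng.integers(config.effort_range[0], config.effort_range[1] + 1, size=n)

    sites: list[Site] = []
    idx = 0
    for ri, s_r in enumerate(config.sites_per_region):
        region = f"R{ri + 1}"
        for j in range(s_r):
            sites.append(
                Site(
                    site_id=f"{region}_s{j + 1:03d}",
                    region_id=region,
                    effort=int(effort[idx]),
                    covariates={
                        name: float(vals[idx, c])
                        for c, name in enumerate(config.covariate_names)
                    },
                )
            )
            idx += 1
    return sites


def generate_community(
    config: GeneratorConfig,
    sites: Sequence[Site],
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Draw coefficients, masses, membership and occupancy states."""
    rng = rng or np.random.default_rng(config.seed + 1)
    R, P = config.n_regions, config.pool_size
    regions = [f"R{r + 1}" for r in range(R)]
    s_max = max(config.sites_per_region)

    species = [f"sp{k + 1:03d}" for k in range(P)]
    log_mass = rng.normal(config.mass_log_mean, config.mass_log_sd, size=P)
    mass_kg = np.exp(log_mass)
    sd = log_mass.std(ddof=0)
    lm_std = (log_mass - log_mass.mean()) / (sd if sd > 0 else 1.0)

    design, _spec = standardize_covariates(sites, ("dRiv", "dSettl", "forCover"))

    beta0 = rng.normal(config.mu_beta0, config.sigma_beta0, size=(R, P))
    alpha0 = rng.normal(config.mu_alpha0, config.sigma_alpha0, size=(R, P))
    psi_slopes = np.stack(
        [
            rng.normal(config.mu_beta2, config.sigma_beta2, size=(R, P)),
            rng.normal(config.mu_beta3, config.sigma_beta3, size=(R, P)),
            rng.normal(config.mu_beta4, config.sigma_beta4, size=(R, P)),
        ],
        axis=2,
    )
    p_slopes = rng.normal(config.mu_alpha2, config.sigma_alpha2, size=(R, P, 1))

    # membership: species-level range effect induces wide-ranging species
    u = (
        rng.normal(0.0, config.species_range_sd, size=P)
        if config.species_range_sd > 0
        else np.zeros(P)
    )
    member_prob = expit(logit(config.omega_by_region)[:, None] + u[None, :])
    w = (rng.random((R, P)) < member_prob).astype(int)

    psi = np.zeros((R, P, s_max))
    p = np.zeros((R, P, s_max))
    z = np.zeros((R, P, s_max), dtype=int)
    site_mask = np.zeros((R, s_max), dtype=bool)
    for ri, region in enumerate(regions):
        s_r = config.sites_per_region[ri]
        site_mask[ri, :s_r] = True
        x = design[region]  # (S_r, 3): dRiv, dSettl, forCover
        eta_psi = (
            beta0[ri][:, None]
            + config.beta1 * lm_std[:, None]
            + psi_slopes[ri] @ x.T
        )
        eta_p = (
            alpha0[ri][:, None]
            + config.alpha1 * lm_std[:, None]
            + p_slopes[ri][:, 0][:, None] * x[:, 1][None, :]
        )
        psi[ri, :, :s_r] = expit(eta_psi)
        p[ri, :, :s_r] = expit(eta_p)
        z[ri, :, :s_r] = (
            rng.random((P, s_r)) < w[ri][:, None] * psi[ri, :, :s_r]
        ).astype(int)

    return SyntheticTruth(
        species=species,
        mass_kg=mass_kg,
        logmass_std=lm_std,
        omega=config.omega_by_region.copy(),
        w=w,
        z=z,
        psi=psi,
        p=p,
        site_mask=site_mask,
        beta0=beta0,
        psi_slopes=psi_slopes,
        alpha0=alpha0,
        p_slopes=p_slopes,
        beta1=config.beta1,
        alpha1=config.alpha1,
    )


def generate_detections(
    truth: SyntheticTruth,
    sites: Sequence[Site],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> DetectionData:
    """Draw detection counts y ~ Binomial(effort, z * p) and assemble
    the observed dataset (species never detected in a region are absent
    from that region's species list; they remain in the truth)."""
    rng = rng or np.random.default_rng(config.seed + 2)
    regions = [f"R{r + 1}" for r in range(config.n_regions)]
    sites_by_region: dict[str, list[Site]] = {r: [] for r in regions}
    for s in sites:
        sites_by_region[s.region_id].append(s)

    species_by_region: dict[str, list[str]] = {}
    y_by_region: dict[str, np.ndarray] = {}
    for ri, region in enumerate(regions):
        rsites = sites_by_region[region]
        s_r = len(rsites)
        effort = np.array([s.effort for s in rsites])
        zp = truth.z[ri, :, :s_r] * truth.p[ri, :, :s_r]
        y_full = rng.binomial(effort[None, :], zp)
        detected = np.flatnonzero(y_full.sum(axis=1) > 0)
        species_by_region[region] = [truth.species[k] for k in detected]
        y_by_region[region] = y_full[detected]

    data = DetectionData(
        regions=regions,
        sites_by_region=sites_by_region,
        species_by_region=species_by_region,
        y=y_by_region,
    )
    data.validate()
    return data


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[Site], SyntheticTruth, DetectionData, list[SpeciesRecord]]:
    """Full pipeline: sites -> truth -> detections -> traits.

    All randomness derives from ``config.seed`` through three
    dedicated child streams, so the same configuration always yields
    byte-identical data.
    """
    root = np.random.SeedSequence(config.seed)
    rng_cov, rng_comm, rng_det = (np.random.default_rng(s) for s in root.spawn(3))
    sites = generate_covariates(config, rng_cov)
    truth = generate_community(config, sites, rng_comm)
    data = generate_detections(truth, sites, config, rng_det)
    mass = dict(zip(truth.species, truth.mass_kg))
    traits = [
        SpeciesRecord(species_id=sp, mass_kg=float(mass[sp]))
        for sp in data.all_species
    ]
    return sites, truth, data, traits


def write_dataset(config: GeneratorConfig, out_dir: str | Path) -> None:
    """Write sites.csv, detections.csv, traits.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites, truth, data, traits = generate_dataset(config)
    write_sites_csv(sites, out / "sites.csv")
    write_detections_csv(data, out / "detections.csv")
    write_traits_csv(traits, out / "traits.csv")
    (out / "truth.json").write_text(truth.to_json())
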