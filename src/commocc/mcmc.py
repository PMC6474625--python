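"""Metropolis-within-Gibbs sampler for the community occupancy model.

One sweep updates, in order: the membership indicators ``w`` of the
augmented slots (with the site occupancy states marginalized out), the
occupancy states ``z`` given ``w``, the data-augmentation parameters
``Omega_r`` (random-walk Metropolis on the logit scale), the
species-region occupancy and detection coefficients (elementwise
random-walk Metropolis against the Bernoulli/Binomial likelihood, or an
exact draw from the hyperdistribution for slots whose likelihood is
vacuous), the community-level mass slopes, the latent log-masses of
augmented slots, and finally the community hyper-means and hyper-SDs by
conjugate (truncated) draws.

Proposal scales adapt during burn-in only (Robbins-Monro toward an
acceptance rate of 0.44) and are frozen afterwards, preserving detailed
balance for every retained draw. Each chain draws from its own RNG
stream spawned from the master seed, so results are reproducible and
independent of how many chains run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, gammaincc, gammainccinv, logit, ndtr, ndtri

from .model import ModelData, ParamState, PriorSpec

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "GibbsKernel",
    "gibbs_step",
    "run_chains",
    "gelman_rubin",
]

_TARGET_ACC = 0.44
_PCLIP = 1e-12


@dataclass
class McmcConfig:
    """MCMC schedule and proposal settings.

    The default schedule is the full production run: 3 chains of
    50,000 iterations, 5,000 burn-in, thinning by 10, retaining
    3 x 4,500 = 13,500 draws.
    """

    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    n_chains: int = 3
    proposal_scales: dict = field(default_factory=dict)
    adapt: bool = True
    seed: int = 0
    monitor_species: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain


@dataclass
class PosteriorDraws:
    """Retained draws: array (chain, retained-iteration, parameter)."""

    names: list[str]
    draws: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.names)}

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_retained) draws of one parameter."""
        return self.draws[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        n_c, n_r, _ = self.draws.shape
        frames = []
        for c in range(n_c):
            df = pd.DataFrame(self.draws[c], columns=self.names)
            df.insert(0, "iter", np.arange(n_r))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        long = self.to_dataframe().melt(
            id_vars=["chain", "iter"], var_name="parameter", value_name="value"
        )
        # shortest round-trip repr keeps the store bit-exact
        long["value"] = long["value"].map(repr)
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorDraws":
        long = pd.read_csv(path, float_precision="round_trip")
        wide = long.pivot_table(
            index=["chain", "iter"], columns="parameter", values="value", sort=False
        )
        names = list(wide.columns)
        chains = sorted(long["chain"].unique())
        arr = np.stack([wide.loc[c].to_numpy() for c in chains])
        return cls(names=names, draws=arr)


def _norm_logpdf(x, mean, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _dprior_normal(val, delta, mean, sd):
    """log N(val+delta) - log N(val) for a Normal(mean, sd) prior."""
    return ((val - mean) ** 2 - (val + delta - mean) ** 2) / (2.0 * sd**2)


def _trunc_normal(mean, sd, lo, hi, u):
    """Inverse-CDF draw from Normal(mean, sd) truncated to [lo, hi]."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    q = np.clip(a + u * (b - a), 1e-14, 1 - 1e-14)
    return np.clip(mean + sd * ndtri(q), lo, hi)


def _trunc_invgamma_var(a, ss_half, ub_var, u):
    """Draw a variance from InvGamma(a, ss_half) truncated to (0, ub_var].

    Uses F(x) = Q(a, ss_half / x) with Q the regularized upper
    incomplete gamma function.
    """
    a = np.asarray(a, dtype=float)
    ss_half = np.maximum(np.asarray(ss_half, dtype=float), 1e-12)
    f_ub = gammaincc(a, ss_half / ub_var)
    q = np.clip(u * f_ub, 1e-300, 1.0)
    t = gammainccinv(a, q)
    with np.errstate(divide="ignore"):
        tau = np.where(t > 0.0, ss_half / np.where(t > 0.0, t, 1.0), np.inf)
    tau = np.where(f_ub <= 0.0, ub_var, tau)
    return np.minimum(tau, ub_var)


class GibbsKernel:
    """Stateful sweep operator bound to one dataset and prior."""

    def __init__(
        self,
        data: ModelData,
        priors: PriorSpec,
        proposal_scales: dict | None = None,
    ):
        self.data = data
        self.priors = priors
        self.C_psi = data.x_psi.shape[2]
        self.C_p = data.x_p.shape[2]
        self.re_mass = data.config.mass_random_slopes

        self.mask3 = data.site_mask[:, None, :]  # (R,1,S)
        self.eff3 = data.effort[:, None, :].astype(float)
        self.aug = ~data.observed  # (R,M)
        self.psi_cov_names = list(data.config.psi_covariates)
        self.p_cov_names = list(data.config.p_covariates)

        families = ["beta0", "alpha0"]
        families += [f"beta_{n}" for n in self.psi_cov_names]
        families += [f"alpha_{n}" for n in self.p_cov_names]
        blocks = ["omega", "beta_mass", "alpha_mass", "logmass"] + families
        # joint hyper moves: translate (mu + all effects) and rescale
        # (sigma + all deviations), one scalar proposal per family
        blocks += [f"tr_{f}" for f in families] + [f"rs_{f}" for f in families]
        defaults = {b: 0.5 for b in blocks}
        defaults.update({"omega": 0.4, "beta_mass": 0.1, "alpha_mass": 0.1})
        defaults.update({f"tr_{f}": 0.2 for f in families})
        defaults.update({f"rs_{f}": 0.3 for f in families})
        if proposal_scales:
            defaults.update(proposal_scales)
        self.log_scales = {b: float(np.log(s)) for b, s in defaults.items()}
        self.acc_accum: dict[str, list[float]] = {b: [0.0, 0.0] for b in self.log_scales}

    # -- linear predictors -------------------------------------------------
    def _eta_psi(self, st: ParamState) -> np.ndarray:
        eta = (st.beta0 + np.asarray(st.beta1_full) * st.logmass)[:, :, None]
        if self.C_psi:
            eta = eta + np.einsum("rkc,rsc->rks", st.psi_slopes, self.data.x_psi)
        return eta

    def _eta_p(self, st: ParamState) -> np.ndarray:
        eta = (st.alpha0 + np.asarray(st.alpha1_full) * st.logmass)[:, :, None]
        if self.C_p:
            eta = eta + np.einsum("rkc,rsc->rks", st.p_slopes, self.data.x_p)
        return eta

    def _ll_psi(self, eta: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Per-slot Bernoulli log-likelihood of z given logit(psi)=eta."""
        return ((z * eta - np.logaddexp(0.0, eta)) * self.mask3).sum(axis=2)

    def _ll_p(self, eta: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Per-slot Binomial log-likelihood of y over occupied sites."""
        y = self.data.y
        return ((y * eta - self.eff3 * np.logaddexp(0.0, eta)) * (z * self.mask3)).sum(
            axis=2
        )

    # -- initialization ----------------------------------------------------
    def init_state(self, rng: np.random.Generator) -> ParamState:
        d = self.data
        R, M, S = d.R, d.M, d.S
        n_obs = d.n_obs.astype(float)
        omega = (n_obs + 1.0) / (M + 2.0)

        obs = d.observed
        det_frac = ((d.y > 0).sum(axis=2) + 0.5) / (d.site_mask.sum(axis=1)[:, None] + 1.0)
        base_psi = float(np.clip(det_frac[obs].mean() if obs.any() else 0.3, 0.05, 0.9))
        tot_eff = d.effort.sum(axis=1)[:, None]
        det_rate = (d.y.sum(axis=2) + 0.5) / (tot_eff + 1.0)
        base_p = float(np.clip(det_rate[obs].mean() if obs.any() else 0.1, 0.01, 0.5))

        mu_b0 = float(logit(base_psi))
        mu_a0 = float(logit(base_p))
        beta0 = mu_b0 + 0.3 * rng.standard_normal((R, M))
        alpha0 = mu_a0 + 0.3 * rng.standard_normal((R, M))
        psi_slopes = 0.05 * rng.standard_normal((R, M, self.C_psi))
        p_slopes = 0.05 * rng.standard_normal((R, M, self.C_p))

        lm_obs = d.logmass_obs
        mu_mass = np.zeros(R)
        sigma_mass = np.ones(R)
        for r in range(R):
            vals = lm_obs[r][obs[r]]
            if vals.size:
                mu_mass[r] = vals.mean()
                sigma_mass[r] = max(vals.std(ddof=0), 0.2)
        logmass = np.where(
            np.isnan(lm_obs),
            mu_mass[:, None] + sigma_mass[:, None] * rng.standard_normal((R, M)),
            lm_obs,
        )

        w = (obs | (rng.random((R, M)) < omega[:, None])).astype(int)
        z = ((d.y > 0) | ((rng.random((R, M, S)) < base_psi) & (w[:, :, None] == 1))).astype(int)
        z *= self.mask3.astype(int)
        z *= w[:, :, None]
        z[d.y > 0] = 1

        return ParamState(
            omega=omega,
            mu_beta0=mu_b0,
            sigma_beta0=0.5,
            mu_alpha0=mu_a0,
            sigma_alpha0=0.5,
            beta1=0.0,
            alpha1=0.0,
            mu_psi_slopes=np.zeros(self.C_psi),
            sigma_psi_slopes=np.full(self.C_psi, 0.25),
            mu_p_slopes=np.zeros(self.C_p),
            sigma_p_slopes=np.full(self.C_p, 0.25),
            beta0=beta0,
            psi_slopes=psi_slopes,
            alpha0=alpha0,
            p_slopes=p_slopes,
            mu_mass=mu_mass,
            sigma_mass=sigma_mass,
            logmass=logmass,
            w=w,
            z=z,
            beta1_dev=np.zeros((R, M)) if self.re_mass else None,
            alpha1_dev=np.zeros((R, M)) if self.re_mass else None,
        )

    # -- one sweep ----------------------------------------------------------
    def sweep(self, st: ParamState, rng: np.random.Generator) -> dict[str, float]:
        d = self.data
        R, M, S = d.R, d.M, d.S
        pri = self.priors
        acc_rates: dict[str, float] = {}

        eta_psi = self._eta_psi(st)
        eta_p = self._eta_p(st)
        psi = np.clip(expit(eta_psi), _PCLIP, 1 - _PCLIP)
        p = np.clip(expit(eta_p), 0.0, 1 - 1e-12)

        # ---- (w, z) joint block: w with z marginalized, then z | w
        log_miss = self.eff3 * np.log1p(-p)
        miss = np.exp(log_miss)
        log_l1 = (np.log(psi * miss + (1.0 - psi)) * self.mask3).sum(axis=2)
        lo_om = logit(np.clip(st.omega, 1e-15, 1 - 1e-15))
        pw1 = expit(lo_om[:, None] + log_l1)
        st.w = np.where(d.observed, 1, (rng.random((R, M)) < pw1).astype(int))

        pz = psi * miss / (psi * miss + (1.0 - psi))
        pz = np.where(d.y > 0, 1.0, pz)
        z = (rng.random((R, M, S)) < pz).astype(int)
        z *= st.w[:, :, None]
        z *= self.mask3.astype(int)
        z[(d.y > 0) & np.broadcast_to(self.mask3, d.y.shape)] = 1
        st.z = z

        # ---- Omega (logit-scale random walk)
        s_om = np.exp(self.log_scales["omega"])
        sw = st.w.sum(axis=1).astype(float)
        prop = lo_om + s_om * rng.standard_normal(R)

        def omega_lp(l):
            return (
                sw * l
                - M * np.logaddexp(0.0, l)
                + _norm_logpdf(l, pri.omega_logit_mean, pri.omega_logit_sd)
            )

        acc = np.log(rng.random(R)) < omega_lp(prop) - omega_lp(lo_om)
        lo_om = np.where(acc, prop, lo_om)
        st.omega = expit(lo_om)
        acc_rates["omega"] = float(acc.mean())

        # ---- occupancy coefficients
        w1 = st.w == 1
        n_w1 = max(int(w1.sum()), 1)
        ll_psi = self._ll_psi(eta_psi, z)

        def psi_block(name, values, design_col, mu, sd):
            nonlocal eta_psi, ll_psi
            s = np.exp(self.log_scales[name])
            delta = s * rng.standard_normal((R, M))
            eta_new = (
                eta_psi + delta[:, :, None]
                if design_col is None
                else eta_psi + delta[:, :, None] * design_col
            )
            ll_new = self._ll_psi(eta_new, z)
            dpost = ll_new - ll_psi + _dprior_normal(values, delta, mu, sd)
            acc = (np.log(rng.random((R, M))) < dpost) & w1
            step = np.where(acc, delta, 0.0)
            values += step
            eta_psi = (
                eta_psi + step[:, :, None]
                if design_col is None
                else eta_psi + step[:, :, None] * design_col
            )
            ll_psi = np.where(acc, ll_new, ll_psi)
            # vacuous-likelihood slots: exact draw from the hyperdistribution
            fresh = mu + sd * rng.standard_normal((R, M))
            values[~w1] = fresh[~w1]
            acc_rates[name] = float(acc.sum() / n_w1)

        psi_block("beta0", st.beta0, None, st.mu_beta0, st.sigma_beta0)
        for c, nm in enumerate(self.psi_cov_names):
            psi_block(
                f"beta_{nm}",
                st.psi_slopes[:, :, c],
                d.x_psi[:, :, c][:, None, :],
                st.mu_psi_slopes[c],
                st.sigma_psi_slopes[c],
            )

        # community-level mass slope on occupancy
        lm3 = st.logmass[:, :, None]
        s_b1 = np.exp(self.log_scales["beta_mass"])
        delta1 = s_b1 * rng.standard_normal()
        u1 = np.log(rng.random())
        if pri.slope_lo <= st.beta1 + delta1 <= pri.slope_hi:
            eta_new = eta_psi + delta1 * lm3
            ll_new = self._ll_psi(eta_new, z)
            if u1 < (ll_new - ll_psi)[w1].sum():
                st.beta1 += delta1
                eta_psi = eta_new
                ll_psi = ll_new
                acc_rates["beta_mass"] = 1.0
            else:
                acc_rates["beta_mass"] = 0.0
        else:
            acc_rates["beta_mass"] = 0.0
        if self.re_mass:
            # species-region deviations around the community mass slope
            s_dev = np.exp(self.log_scales["beta_mass"])
            delta = s_dev * rng.standard_normal((R, M))
            eta_new = eta_psi + (delta * st.logmass)[:, :, None]
            ll_new = self._ll_psi(eta_new, z)
            dpost = ll_new - ll_psi + _dprior_normal(st.beta1_dev, delta, 0.0, st.sigma_beta1)
            acc = (np.log(rng.random((R, M))) < dpost) & w1
            step = np.where(acc, delta, 0.0)
            st.beta1_dev += step
            eta_psi = eta_psi + (step * st.logmass)[:, :, None]
            ll_psi = np.where(acc, ll_new, ll_psi)
            fresh = st.sigma_beta1 * rng.standard_normal((R, M))
            st.beta1_dev[~w1] = fresh[~w1]

        # ---- joint hyper moves for occupancy families
        psi_families = [
            (
                "beta0",
                st.beta0,
                None,
                lambda: st.mu_beta0,
                lambda v: setattr(st, "mu_beta0", float(v)),
                lambda: st.sigma_beta0,
                lambda v: setattr(st, "sigma_beta0", float(v)),
                ("normal", pri.hypermean_mean, pri.hypermean_sd),
            )
        ]
        for c, nm in enumerate(self.psi_cov_names):
            psi_families.append(
                (
                    f"beta_{nm}",
                    st.psi_slopes[:, :, c],
                    d.x_psi[:, :, c][:, None, :],
                    (lambda c=c: st.mu_psi_slopes[c]),
                    (lambda v, c=c: st.mu_psi_slopes.__setitem__(c, float(v))),
                    (lambda c=c: st.sigma_psi_slopes[c]),
                    (lambda v, c=c: st.sigma_psi_slopes.__setitem__(c, float(v))),
                    ("uniform", pri.slope_lo, pri.slope_hi),
                )
            )

        def joint_moves(families, ll_fun, ll_mask, eta_get, eta_set, ll_get, ll_set):
            # translate: shift hyper-mean and every random effect together;
            # rescale: scale hyper-SD and every deviation together
            # (acceptance ratio = delta-loglik + eps, the prior and Jacobian
            # terms of the scaling cancelling up to the single sigma factor)
            for fam, values, col, get_mu, set_mu, get_sig, set_sig, mu_prior in families:
                s = np.exp(self.log_scales[f"tr_{fam}"])
                delta = s * rng.standard_normal()
                u = np.log(rng.random())
                mu = float(get_mu())
                acc_rates[f"tr_{fam}"] = 0.0
                if mu_prior[0] == "uniform":
                    ok = mu_prior[1] <= mu + delta <= mu_prior[2]
                    dpr = 0.0
                else:
                    ok = True
                    dpr = float(_dprior_normal(mu, delta, mu_prior[1], mu_prior[2]))
                if ok:
                    eta_new = (
                        eta_get() + delta if col is None else eta_get() + delta * col
                    )
                    ll_new = ll_fun(eta_new)
                    if u < (ll_new - ll_get())[ll_mask].sum() + dpr:
                        values += delta
                        set_mu(mu + delta)
                        eta_set(eta_new)
                        ll_set(ll_new)
                        acc_rates[f"tr_{fam}"] = 1.0

                s = np.exp(self.log_scales[f"rs_{fam}"])
                eps = s * rng.standard_normal()
                u = np.log(rng.random())
                cfac = float(np.exp(eps))
                sig = float(get_sig())
                acc_rates[f"rs_{fam}"] = 0.0
                if 0.0 < sig * cfac <= pri.sd_upper:
                    mu = float(get_mu())
                    shift = (cfac - 1.0) * (values - mu)
                    eta_new = (
                        eta_get() + shift[:, :, None]
                        if col is None
                        else eta_get() + shift[:, :, None] * col
                    )
                    ll_new = ll_fun(eta_new)
                    if u < (ll_new - ll_get())[ll_mask].sum() + eps:
                        values += shift
                        set_sig(sig * cfac)
                        eta_set(eta_new)
                        ll_set(ll_new)
                        acc_rates[f"rs_{fam}"] = 1.0

        def _set_eta_psi(v):
            nonlocal eta_psi
            eta_psi = v

        def _set_ll_psi(v):
            nonlocal ll_psi
            ll_psi = v

        joint_moves(
            psi_families,
            lambda eta: self._ll_psi(eta, z),
            w1,
            lambda: eta_psi,
            _set_eta_psi,
            lambda: ll_psi,
            _set_ll_psi,
        )

        # ---- detection coefficients
        occ3 = (z * self.mask3).astype(float)
        has_occ = occ3.sum(axis=2) > 0  # implies w == 1
        n_occ = max(int(has_occ.sum()), 1)
        ll_p = self._ll_p(eta_p, z)

        def p_block(name, values, design_col, mu, sd):
            nonlocal eta_p, ll_p
            s = np.exp(self.log_scales[name])
            delta = s * rng.standard_normal((R, M))
            eta_new = (
                eta_p + delta[:, :, None]
                if design_col is None
                else eta_p + delta[:, :, None] * design_col
            )
            ll_new = self._ll_p(eta_new, z)
            dpost = ll_new - ll_p + _dprior_normal(values, delta, mu, sd)
            acc = (np.log(rng.random((R, M))) < dpost) & has_occ
            step = np.where(acc, delta, 0.0)
            values += step
            eta_p = (
                eta_p + step[:, :, None]
                if design_col is None
                else eta_p + step[:, :, None] * design_col
            )
            ll_p = np.where(acc, ll_new, ll_p)
            fresh = mu + sd * rng.standard_normal((R, M))
            values[~has_occ] = fresh[~has_occ]
            acc_rates[name] = float(acc.sum() / n_occ)

        p_block("alpha0", st.alpha0, None, st.mu_alpha0, st.sigma_alpha0)
        for c, nm in enumerate(self.p_cov_names):
            p_block(
                f"alpha_{nm}",
                st.p_slopes[:, :, c],
                d.x_p[:, :, c][:, None, :],
                st.mu_p_slopes[c],
                st.sigma_p_slopes[c],
            )

        s_a1 = np.exp(self.log_scales["alpha_mass"])
        delta1 = s_a1 * rng.standard_normal()
        u1 = np.log(rng.random())
        if pri.slope_lo <= st.alpha1 + delta1 <= pri.slope_hi:
            eta_new = eta_p + delta1 * st.logmass[:, :, None]
            ll_new = self._ll_p(eta_new, z)
            if u1 < (ll_new - ll_p)[has_occ].sum():
                st.alpha1 += delta1
                eta_p = eta_new
                ll_p = ll_new
                acc_rates["alpha_mass"] = 1.0
            else:
                acc_rates["alpha_mass"] = 0.0
        else:
            acc_rates["alpha_mass"] = 0.0
        if self.re_mass:
            s_dev = np.exp(self.log_scales["alpha_mass"])
            delta = s_dev * rng.standard_normal((R, M))
            eta_new = eta_p + (delta * st.logmass)[:, :, None]
            ll_new = self._ll_p(eta_new, z)
            dpost = ll_new - ll_p + _dprior_normal(st.alpha1_dev, delta, 0.0, st.sigma_alpha1)
            acc = (np.log(rng.random((R, M))) < dpost) & has_occ
            step = np.where(acc, delta, 0.0)
            st.alpha1_dev += step
            eta_p = eta_p + (step * st.logmass)[:, :, None]
            ll_p = np.where(acc, ll_new, ll_p)
            fresh = st.sigma_alpha1 * rng.standard_normal((R, M))
            st.alpha1_dev[~has_occ] = fresh[~has_occ]

        # ---- joint hyper moves for detection families
        p_families = [
            (
                "alpha0",
                st.alpha0,
                None,
                lambda: st.mu_alpha0,
                lambda v: setattr(st, "mu_alpha0", float(v)),
                lambda: st.sigma_alpha0,
                lambda v: setattr(st, "sigma_alpha0", float(v)),
                ("normal", pri.hypermean_mean, pri.hypermean_sd),
            )
        ]
        for c, nm in enumerate(self.p_cov_names):
            p_families.append(
                (
                    f"alpha_{nm}",
                    st.p_slopes[:, :, c],
                    d.x_p[:, :, c][:, None, :],
                    (lambda c=c: st.mu_p_slopes[c]),
                    (lambda v, c=c: st.mu_p_slopes.__setitem__(c, float(v))),
                    (lambda c=c: st.sigma_p_slopes[c]),
                    (lambda v, c=c: st.sigma_p_slopes.__setitem__(c, float(v))),
                    ("uniform", pri.slope_lo, pri.slope_hi),
                )
            )

        def _set_eta_p(v):
            nonlocal eta_p
            eta_p = v

        def _set_ll_p(v):
            nonlocal ll_p
            ll_p = v

        joint_moves(
            p_families,
            lambda eta: self._ll_p(eta, z),
            has_occ,
            lambda: eta_p,
            _set_eta_p,
            lambda: ll_p,
            _set_ll_p,
        )

        # ---- latent log-masses of augmented slots
        latent = self.aug
        s_lm = np.exp(self.log_scales["logmass"])
        delta = s_lm * rng.standard_normal((R, M))
        b1 = np.broadcast_to(np.asarray(st.beta1_full, dtype=float), (R, M))
        a1 = np.broadcast_to(np.asarray(st.alpha1_full, dtype=float), (R, M))
        eta_psi_new = eta_psi + (b1 * delta)[:, :, None]
        eta_p_new = eta_p + (a1 * delta)[:, :, None]
        dll = (self._ll_psi(eta_psi_new, z) - ll_psi) + (self._ll_p(eta_p_new, z) - ll_p)
        dpr = _dprior_normal(st.logmass, delta, st.mu_mass[:, None], st.sigma_mass[:, None])
        mh_mask = latent & w1
        acc = (np.log(rng.random((R, M))) < dll + dpr) & mh_mask
        st.logmass += np.where(acc, delta, 0.0)
        acc_rates["logmass"] = float(acc.sum() / max(int(mh_mask.sum()), 1))
        fresh = st.mu_mass[:, None] + st.sigma_mass[:, None] * rng.standard_normal((R, M))
        gibbs_lm = latent & ~w1
        st.logmass[gibbs_lm] = fresh[gibbs_lm]

        # ---- hyper-means
        n = float(R * M)
        # mu_beta0, mu_alpha0: Normal prior
        for attr, coef, sig in (
            ("mu_beta0", st.beta0, st.sigma_beta0),
            ("mu_alpha0", st.alpha0, st.sigma_alpha0),
        ):
            prec = n / sig**2 + 1.0 / pri.hypermean_sd**2
            mean = (coef.sum() / sig**2 + pri.hypermean_mean / pri.hypermean_sd**2) / prec
            setattr(st, attr, float(mean + rng.standard_normal() / np.sqrt(prec)))
        # slope hyper-means: Uniform prior -> truncated Normal draw (batched)
        n_slopes = self.C_psi + self.C_p
        if n_slopes:
            means = np.concatenate(
                [st.psi_slopes.mean(axis=(0, 1)), st.p_slopes.mean(axis=(0, 1))]
            )
            sds = np.concatenate([st.sigma_psi_slopes, st.sigma_p_slopes]) / np.sqrt(n)
            u = rng.random(n_slopes)
            draws = _trunc_normal(means, sds, pri.slope_lo, pri.slope_hi, u)
            st.mu_psi_slopes = draws[: self.C_psi]
            st.mu_p_slopes = draws[self.C_psi :]
        # region mass means: Normal prior, data = all pool slots
        prec_m = M / st.sigma_mass**2 + 1.0 / pri.mass_mean_sd**2
        mean_m = (st.logmass.sum(axis=1) / st.sigma_mass**2) / prec_m
        st.mu_mass = mean_m + rng.standard_normal(R) / np.sqrt(prec_m)

        # ---- hyper-SDs: Uniform(0, upper) prior -> truncated inv-gamma (batched)
        ss = [
            ((st.beta0 - st.mu_beta0) ** 2).sum(),
            ((st.alpha0 - st.mu_alpha0) ** 2).sum(),
        ]
        counts = [n, n]
        uppers = [pri.sd_upper, pri.sd_upper]
        for c in range(self.C_psi):
            ss.append(((st.psi_slopes[:, :, c] - st.mu_psi_slopes[c]) ** 2).sum())
            counts.append(n)
            uppers.append(pri.sd_upper)
        for c in range(self.C_p):
            ss.append(((st.p_slopes[:, :, c] - st.mu_p_slopes[c]) ** 2).sum())
            counts.append(n)
            uppers.append(pri.sd_upper)
        if self.re_mass:
            ss += [(st.beta1_dev**2).sum(), (st.alpha1_dev**2).sum()]
            counts += [n, n]
            uppers += [pri.sd_upper, pri.sd_upper]
        for r in range(R):
            ss.append(((st.logmass[r] - st.mu_mass[r]) ** 2).sum())
            counts.append(float(M))
            uppers.append(pri.mass_sd_upper)
        a = (np.asarray(counts) - 1.0) / 2.0
        tau = _trunc_invgamma_var(
            a, np.asarray(ss) / 2.0, np.asarray(uppers) ** 2, rng.random(len(ss))
        )
        sd_draws = np.sqrt(tau)
        st.sigma_beta0 = float(sd_draws[0])
        st.sigma_alpha0 = float(sd_draws[1])
        pos = 2
        st.sigma_psi_slopes = sd_draws[pos : pos + self.C_psi].copy()
        pos += self.C_psi
        st.sigma_p_slopes = sd_draws[pos : pos + self.C_p].copy()
        pos += self.C_p
        if self.re_mass:
            st.sigma_beta1 = float(sd_draws[pos])
            st.sigma_alpha1 = float(sd_draws[pos + 1])
            pos += 2
        st.sigma_mass = sd_draws[pos : pos + R].copy()

        return acc_rates

    def adapt(self, acc_rates: dict[str, float], t: int) -> None:
        step = min(0.25, 2.0 / np.sqrt(t + 20.0))
        for name, rate in acc_rates.items():
            self.log_scales[name] += step * (rate - _TARGET_ACC)
            self.log_scales[name] = float(np.clip(self.log_scales[name], -8.0, 3.0))

    def track(self, acc_rates: dict[str, float]) -> None:
        for name, rate in acc_rates.items():
            self.acc_accum[name][0] += rate
            self.acc_accum[name][1] += 1.0

    def mean_acceptance(self) -> dict[str, float]:
        return {
            name: (tot / cnt if cnt else float("nan"))
            for name, (tot, cnt) in self.acc_accum.items()
        }


def gibbs_step(
    state: ParamState,
    data: ModelData,
    priors: PriorSpec,
    rng: np.random.Generator,
    kernel: GibbsKernel | None = None,
) -> ParamState:
    """One full Metropolis-within-Gibbs sweep (returns the new state)."""
    kernel = kernel or GibbsKernel(data, priors)
    new = state.copy()
    kernel.sweep(new, rng)
    return new


def monitor_names(data: ModelData, monitor_species: bool = False) -> list[str]:
    names: list[str] = []
    names += [f"Omega[{r}]" for r in data.regions]
    names += [f"N[{r}]" for r in data.regions]
    names += ["mu_beta0", "sigma_beta0", "mu_alpha0", "sigma_alpha0"]
    names += ["beta_mass", "alpha_mass"]
    for nm in data.config.psi_covariates:
        names += [f"mu_beta_{nm}", f"sigma_beta_{nm}"]
    for nm in data.config.p_covariates:
        names += [f"mu_alpha_{nm}", f"sigma_alpha_{nm}"]
    names += [f"mu_mass[{r}]" for r in data.regions]
    names += [f"sigma_mass[{r}]" for r in data.regions]
    names += ["psi_community", "p_community"]
    if monitor_species:
        for ri, r in enumerate(data.regions):
            for k, sp in enumerate(data.species_by_region[r]):
                names.append(f"beta0[{r}:{sp}]")
                names.append(f"alpha0[{r}:{sp}]")
                for nm in data.config.psi_covariates:
                    names.append(f"beta_{nm}[{r}:{sp}]")
                for nm in data.config.p_covariates:
                    names.append(f"alpha_{nm}[{r}:{sp}]")
    return names


def _monitor_vector(st: ParamState, data: ModelData, monitor_species: bool) -> np.ndarray:
    parts = [
        st.omega,
        st.w.sum(axis=1).astype(float),
        [st.mu_beta0, st.sigma_beta0, st.mu_alpha0, st.sigma_alpha0],
        [st.beta1, st.alpha1],
    ]
    for c in range(len(data.config.psi_covariates)):
        parts.append([st.mu_psi_slopes[c], st.sigma_psi_slopes[c]])
    for c in range(len(data.config.p_covariates)):
        parts.append([st.mu_p_slopes[c], st.sigma_p_slopes[c]])
    parts.append(st.mu_mass)
    parts.append(st.sigma_mass)
    parts.append([float(expit(st.mu_beta0)), float(expit(st.mu_alpha0))])
    if monitor_species:
        sp_vals = []
        for ri in range(data.R):
            n_r = int(data.n_obs[ri])
            for k in range(n_r):
                sp_vals.append(st.beta0[ri, k])
                sp_vals.append(st.alpha0[ri, k])
                for c in range(len(data.config.psi_covariates)):
                    sp_vals.append(st.psi_slopes[ri, k, c])
                for c in range(len(data.config.p_covariates)):
                    sp_vals.append(st.p_slopes[ri, k, c])
        parts.append(sp_vals)
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def run_chains(
    data: ModelData, priors: PriorSpec, config: McmcConfig
) -> PosteriorDraws:
    """Run the full multi-chain schedule and collect retained draws.

    Burn-in is discarded first, then thinning applied, so the retained
    count per chain is (n_iter - burn_in) // thin. Derived quantities
    (regional richness N_r, meta-community occupancy/detection on the
    probability scale) are recorded alongside the parameters at every
    retained iteration.
    """
    names = monitor_names(data, config.monitor_species)
    n_ret = config.retained_per_chain
    draws = np.empty((config.n_chains, n_ret, len(names)))
    root = np.random.SeedSequence(config.seed)
    kernels = []
    for ci, child in enumerate(root.spawn(config.n_chains)):
        rng = np.random.default_rng(child)
        kernel = GibbsKernel(data, priors, config.proposal_scales or None)
        st = kernel.init_state(rng)
        pos = 0
        for t in range(config.n_iter):
            acc = kernel.sweep(st, rng)
            if t < config.burn_in:
                if config.adapt:
                    kernel.adapt(acc, t)
            else:
                kernel.track(acc)
                if (t - config.burn_in) % config.thin == config.thin - 1:
                    vec = _monitor_vector(st, data, config.monitor_species)
                    if not np.all(np.isfinite(vec)):
                        raise FloatingPointError(
                            f"non-finite state in chain {ci} at iteration {t}"
                        )
                    draws[ci, pos] = vec
                    pos += 1
        if pos != n_ret:
            raise RuntimeError(f"chain {ci}: retained {pos}, expected {n_ret}")
        kernels.append(kernel)

    meta = {
        "n_iter": config.n_iter,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "n_chains": config.n_chains,
        "seed": config.seed,
        "acceptance": {ci: k.mean_acceptance() for ci, k in enumerate(kernels)},
        "proposal_scales": {
            ci: {b: float(np.exp(s)) for b, s in k.log_scales.items()}
            for ci, k in enumerate(kernels)
        },
        "regions": list(data.regions),
        "n_obs": data.n_obs.tolist(),
    }
    return PosteriorDraws(names=names, draws=draws, meta=meta)


def gelman_rubin(draws: PosteriorDraws | np.ndarray) -> dict[str, float]:
    """Potential scale reduction factor (Gelman-Rubin Rhat) per parameter.

    Classic between/within-chain variance formula on the retained
    draws, floored at 1.0 (the PSRF estimates a ratio that is 1 at
    convergence; sampling noise can push the raw estimate slightly
    below). Requires at least 2 chains of at least 10 draws.
    """
    if isinstance(draws, PosteriorDraws):
        arr = draws.draws
        names = draws.names
    else:
        arr = np.asarray(draws)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        names = [f"param_{i}" for i in range(arr.shape[2])]
    m, n_draws, n_par = arr.shape
    if m < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    if n_draws < 10:
        raise ValueError("gelman_rubin requires at least 10 draws per chain")

    out: dict[str, float] = {}
    chain_means = arr.mean(axis=1)  # (m, P)
    within = arr.var(axis=1, ddof=1).mean(axis=0)  # (P,)
    between = n_draws * chain_means.var(axis=0, ddof=1)  # (P,)
    for j in range(n_par):
        w_j, b_j = within[j], between[j]
        if w_j == 0.0:
            rhat = 1.0 if b_j == 0.0 else float("inf")
        else:
            vhat = (n_draws - 1) / n_draws * w_j + b_j / n_draws
            rhat = max(1.0, float(np.sqrt(vhat / w_j)))
        out[names[j]] = rhat
    return out
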