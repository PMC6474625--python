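import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, norm, uniform

import commocc as co
from commocc.model import (
    ModelConfig,
    ModelData,
    ParamState,
    PriorSpec,
    conditional_w,
    conditional_z,
    detection_prob,
    log_posterior,
    log_prior,
    loglik,
    occupancy_prob,
    prepare_model_data,
)


def tiny_model_data(R=1, M=2, S=2, effort=3, n_psi=1, n_p=1, seed=0):
    rng = np.random.default_rng(seed)
    observed = np.zeros((R, M), dtype=bool)
    observed[:, 0] = True
    y = np.zeros((R, M, S), dtype=int)
    y[:, 0, 0] = 1
    return ModelData(
        regions=[f"R{r+1}" for r in range(R)],
        species_by_region={f"R{r+1}": ["spA"] for r in range(R)},
        M=M,
        y=y,
        effort=np.full((R, S), effort, dtype=int),
        site_mask=np.ones((R, S), dtype=bool),
        observed=observed,
        x_psi=rng.standard_normal((R, S, n_psi)),
        x_p=rng.standard_normal((R, S, n_p)),
        logmass_obs=np.where(observed, 0.3, np.nan),
        config=ModelConfig(
            psi_covariates=tuple(f"x{i}" for i in range(n_psi)),
            p_covariates=tuple(f"u{i}" for i in range(n_p)),
        ),
    )


def tiny_state(data, rng=None, **overrides):
    rng = rng or np.random.default_rng(7)
    R, M, S = data.R, data.M, data.S
    st = ParamState(
        omega=np.full(R, 0.5),
        mu_beta0=0.0,
        sigma_beta0=0.8,
        mu_alpha0=-1.0,
        sigma_alpha0=0.6,
        beta1=0.3,
        alpha1=-0.1,
        mu_psi_slopes=np.full(data.x_psi.shape[2], 0.2),
        sigma_psi_slopes=np.full(data.x_psi.shape[2], 0.4),
        mu_p_slopes=np.full(data.x_p.shape[2], 0.1),
        sigma_p_slopes=np.full(data.x_p.shape[2], 0.3),
        beta0=rng.normal(0, 0.5, (R, M)),
        psi_slopes=rng.normal(0, 0.3, (R, M, data.x_psi.shape[2])),
        alpha0=rng.normal(-1, 0.5, (R, M)),
        p_slopes=rng.normal(0, 0.3, (R, M, data.x_p.shape[2])),
        mu_mass=np.zeros(R),
        sigma_mass=np.ones(R),
        logmass=np.where(np.isnan(data.logmass_obs), 0.1, data.logmass_obs),
        w=np.ones((R, M), dtype=int),
        z=(data.y > 0).astype(int),
    )
    for k, v in overrides.items():
        setattr(st, k, v)
    return st


class TestProbabilitySurfaces:
    def test_all_zero_coefficients_give_half(self):
        data = tiny_model_data()
        st = tiny_state(
            data,
            beta0=np.zeros((1, 2)),
            psi_slopes=np.zeros((1, 2, 1)),
            beta1=0.0,
            logmass=np.zeros((1, 2)),
        )
        np.testing.assert_allclose(occupancy_prob(st, data), 0.5)

    def test_intercept_closed_form(self):
        data = tiny_model_data(n_psi=0, n_p=0)
        st = tiny_state(
            data,
            beta0=np.full((1, 2), 0.23),
            psi_slopes=np.zeros((1, 2, 0)),
            p_slopes=np.zeros((1, 2, 0)),
            beta1=0.0,
        )
        np.testing.assert_allclose(occupancy_prob(st, data), expit(0.23))
        assert expit(0.23) == pytest.approx(0.557248, abs=1e-6)

    def test_detection_inversion_of_004(self):
        assert logit(0.04) == pytest.approx(-3.178054, abs=1e-6)
        data = tiny_model_data(n_psi=0, n_p=0)
        st = tiny_state(
            data,
            alpha0=np.full((1, 2), logit(0.04)),
            p_slopes=np.zeros((1, 2, 0)),
            psi_slopes=np.zeros((1, 2, 0)),
            alpha1=0.0,
        )
        np.testing.assert_allclose(detection_prob(st, data), 0.04, atol=1e-12)

    def test_monotone_in_settlement_distance(self):
        # positive slope on dSettl: psi and p increase away from
        # settlements, holding everything else fixed
        data = tiny_model_data(S=6, n_psi=1, n_p=1)
        data.x_psi[0, :, 0] = np.linspace(-2, 2, 6)
        data.x_p[0, :, 0] = np.linspace(-2, 2, 6)
        st = tiny_state(
            data,
            psi_slopes=np.full((1, 2, 1), 0.23),
            p_slopes=np.full((1, 2, 1), 0.17),
            beta0=np.zeros((1, 2)),
            alpha0=np.zeros((1, 2)),
        )
        psi = occupancy_prob(st, data)
        p = detection_prob(st, data)
        assert (np.diff(psi[0, 0]) > 0).all()
        assert (np.diff(p[0, 0]) > 0).all()


class TestLoglik:
    def test_single_cell_binomial(self):
        ll = loglik(np.array([[1]]), np.array([2]), np.array([[1]]), np.array([[0.5]]))
        assert ll == pytest.approx(np.log(2 * 0.5 * 0.5), abs=1e-12)

    def test_unoccupied_cells(self):
        assert loglik(np.array([[0]]), np.array([3]), np.array([[0]]), np.array([[0.4]])) == 0.0
        assert loglik(np.array([[2]]), np.array([3]), np.array([[0]]), np.array([[0.4]])) == -np.inf

    def test_matches_per_cell_loop_oracle(self, rng):
        K, S = 4, 5
        effort = rng.integers(1, 8, size=S)
        z = rng.integers(0, 2, size=(K, S))
        p = rng.uniform(0.05, 0.9, size=(K, S))
        y = rng.binomial(effort[None, :], z * p)
        got = loglik(y, effort, z, p)
        want = 0.0
        for k in range(K):
            for i in range(S):
                if z[k, i] == 1:
                    want += binom.logpmf(y[k, i], effort[i], p[k, i])
                elif y[k, i] > 0:
                    want = -np.inf
        assert got == pytest.approx(want, abs=1e-10)

    def test_effort_one_reduces_to_bernoulli(self, rng):
        K, S = 3, 6
        z = np.ones((K, S), dtype=int)
        p = rng.uniform(0.1, 0.9, size=(K, S))
        y = rng.integers(0, 2, size=(K, S))
        got = loglik(y, np.ones(S, dtype=int), z, p)
        bern = (y * np.log(p) + (1 - y) * np.log1p(-p)).sum()
        assert got == pytest.approx(bern, abs=1e-12)


class TestDiscreteConditionals:
    def test_detection_forces_occupancy(self):
        pr = conditional_z(np.array([2]), np.array([5]), np.array([0.3]), np.array([0.2]), np.array([1]))
        assert pr[0] == 1.0

    def test_non_member_excluded(self):
        pr = conditional_z(np.array([0]), np.array([5]), np.array([0.3]), np.array([0.2]), np.array([0]))
        assert pr[0] == 0.0

    def test_closed_form_survey_values(self):
        # psi = 0.26, p = 0.04, effort = 31, y = 0
        pr = conditional_z(
            np.array([0]), np.array([31]), np.array([0.26]), np.array([0.04]), np.array([1])
        )
        want = 0.26 * 0.96**31 / (0.26 * 0.96**31 + 0.74)
        assert pr[0] == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(0.0902, abs=5e-4)

    def test_omega_endpoints_and_uninformative_history(self):
        y = np.zeros(1, dtype=int)
        eff = np.array([4])
        assert conditional_w(y, eff, np.array([0.5]), np.array([0.3]), 0.0) == 0.0
        assert conditional_w(y, eff, np.array([0.5]), np.array([0.3]), 1.0) == 1.0
        # an undetectable species carries no information: posterior = Omega
        got = conditional_w(y, np.array([1]), np.array([1.0]), np.array([0.0]), 0.37)
        assert got == pytest.approx(0.37, abs=1e-12)

    def test_detected_slot_rejected(self):
        with pytest.raises(ValueError, match="detected slot"):
            conditional_w(np.array([1, 0]), np.array([3, 3]), np.full(2, 0.5), np.full(2, 0.2), 0.5)

    def test_two_site_enumeration(self):
        # exhaustive enumeration over (w, z1, z2) in {0,1}^3
        psi = np.array([0.4, 0.7])
        p = np.array([0.25, 0.1])
        eff = np.array([3, 2])
        omega = 0.6
        y = np.zeros(2, dtype=int)
        num = den = 0.0
        for w in (0, 1):
            for z1 in (0, 1):
                for z2 in (0, 1):
                    pr = omega if w else 1 - omega
                    for i, zi in enumerate((z1, z2)):
                        pz = w * psi[i]
                        pr *= pz if zi else 1 - pz
                        pr *= binom.pmf(0, eff[i], zi * p[i])
                    den += pr
                    if w:
                        num += pr
        got = conditional_w(y, eff, psi, p, omega)
        assert got == pytest.approx(num / den, abs=1e-12)


class TestConditionalProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st_

    @given(
        psi=st_.floats(0.01, 0.99),
        p=st_.floats(0.0, 0.99),
        effort=st_.integers(1, 60),
        omega=st_.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probabilities_and_monotonicity(self, psi, p, effort, omega):
        y0 = np.array([0])
        eff = np.array([effort])
        pz = conditional_z(y0, eff, np.array([psi]), np.array([p]), np.array([1]))[0]
        assert 0.0 <= pz <= psi + 1e-12  # missing data can only lower belief
        # more effort without detection lowers P(z = 1)
        pz_more = conditional_z(
            y0, np.array([effort + 5]), np.array([psi]), np.array([p]), np.array([1])
        )[0]
        assert pz_more <= pz + 1e-12
        pw = conditional_w(y0, eff, np.array([psi]), np.array([p]), omega)
        assert 0.0 <= pw <= 1.0
        # an all-zero history can only lower the membership belief
        assert pw <= omega + 1e-12


class TestLogPrior:
    def test_slope_support_edges(self):
        data = tiny_model_data()
        st = tiny_state(data, beta1=10.0)
        assert np.isfinite(log_prior(st, PriorSpec(), data))
        st.beta1 = 10.001
        assert log_prior(st, PriorSpec(), data) == -np.inf

    def test_matches_independent_per_term_oracle(self):
        data = tiny_model_data()
        pri = PriorSpec()
        st = tiny_state(data)
        got = log_prior(st, pri, data)

        want = 0.0
        want += norm.logpdf(logit(st.omega), pri.omega_logit_mean, pri.omega_logit_sd).sum()
        want += norm.logpdf(st.mu_beta0, 0, pri.hypermean_sd)
        want += norm.logpdf(st.mu_alpha0, 0, pri.hypermean_sd)
        for v in (st.beta1, st.alpha1, st.mu_psi_slopes[0], st.mu_p_slopes[0]):
            want += uniform.logpdf(v, pri.slope_lo, pri.slope_hi - pri.slope_lo)
        for s in (st.sigma_beta0, st.sigma_alpha0, st.sigma_psi_slopes[0], st.sigma_p_slopes[0]):
            want += uniform.logpdf(s, 0, pri.sd_upper)
        want += uniform.logpdf(st.sigma_mass, 0, pri.mass_sd_upper).sum()
        want += norm.logpdf(st.mu_mass, 0, pri.mass_mean_sd).sum()
        want += norm.logpdf(st.beta0, st.mu_beta0, st.sigma_beta0).sum()
        want += norm.logpdf(st.alpha0, st.mu_alpha0, st.sigma_alpha0).sum()
        want += norm.logpdf(st.psi_slopes[:, :, 0], st.mu_psi_slopes[0], st.sigma_psi_slopes[0]).sum()
        want += norm.logpdf(st.p_slopes[:, :, 0], st.mu_p_slopes[0], st.sigma_p_slopes[0]).sum()
        want += norm.logpdf(st.logmass, st.mu_mass[:, None], st.sigma_mass[:, None]).sum()
        om = st.omega[:, None]
        want += (st.w * np.log(om) + (1 - st.w) * np.log(1 - om)).sum()
        psi = occupancy_prob(st, data)
        wz = st.w[:, :, None] * psi
        want += np.where(st.z == 1, np.log(wz), np.log1p(-wz)).sum()

        assert got == pytest.approx(want, abs=1e-9)

    def test_doubling_sigma_at_the_mean_costs_log_determinant(self):
        data = tiny_model_data()
        st = tiny_state(data, beta0=np.full((1, 2), 0.0), mu_beta0=0.0)
        pri = PriorSpec()
        base = log_prior(st, pri, data)
        st2 = st.copy()
        st2.sigma_beta0 = 2 * st.sigma_beta0
        n = st.beta0.size
        assert log_prior(st2, pri, data) - base == pytest.approx(-n * np.log(2), abs=1e-10)

    def test_posterior_factorizes(self):
        data = tiny_model_data()
        pri = PriorSpec()
        st = tiny_state(data)
        p = detection_prob(st, data)
        ll = loglik(data.y, data.effort[:, None, :], st.z, p, data.site_mask[:, None, :])
        assert log_posterior(st, pri, data) == pytest.approx(
            log_prior(st, pri, data) + ll, abs=1e-10
        )


class TestPrepareModelData:
    def test_bernoulli_mode_collapses_counts(self, reduced_dataset):
        _, sites, truth, data, traits = reduced_dataset
        aug = co.augment(data, 40)
        md = prepare_model_data(aug, traits, ModelConfig(observation="bernoulli"))
        assert md.y.max() <= 1
        assert set(np.unique(md.effort)) <= {0, 1}

    def test_mass_standardized_over_observed_species(self, reduced_dataset):
        _, sites, truth, data, traits = reduced_dataset
        md = prepare_model_data(co.augment(data, 40), traits)
        lm = md.logmass_obs[md.observed]
        per_species = {}
        for ri, r in enumerate(data.regions):
            for k, sp in enumerate(data.species_by_region[r]):
                per_species[sp] = md.logmass_obs[ri, k]
        vals = np.array(list(per_species.values()))
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
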