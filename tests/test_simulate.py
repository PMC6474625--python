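import numpy as np
import pytest

import commocc as co
from commocc.domain import detections_to_records
from commocc.model import loglik
from commocc.simulate import (
    GeneratorConfig,
    generate_community,
    generate_covariates,
    generate_dataset,
    generate_detections,
    study_scale,
)


class TestGenerateCovariates:
    def test_study_preset_dimensions(self):
        sites = generate_covariates(study_scale(seed=1))
        assert len(sites) == 164
        counts = {}
        for s in sites:
            counts[s.region_id] = counts.get(s.region_id, 0) + 1
        assert list(counts.values()) == [51, 34, 26, 25, 28]
        assert all(12 <= s.effort <= 49 for s in sites)

    def test_requested_correlation_recovered(self):
        cfg = study_scale(seed=9).replace(
            n_regions=1, sites_per_region=(500,), species_range_sd=0.0
        )
        sites = generate_covariates(cfg)
        a = np.array([s.covariates["dSettl"] for s in sites])
        b = np.array([s.covariates["dBound"] for s in sites])
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(0.65, abs=0.1)
        f = np.array([s.covariates["forCover"] for s in sites])
        o = np.array([s.covariates["openCover"] for s in sites])
        assert np.corrcoef(f, o)[0, 1] == pytest.approx(-0.82, abs=0.1)

    def test_non_positive_definite_correlation_rejected(self):
        bad = np.ones((5, 5))
        bad[0, 1] = bad[1, 0] = 2.0
        with pytest.raises(ValueError, match="positive definite"):
            generate_covariates(study_scale(seed=1).replace(covariate_corr=bad))

    def test_same_seed_same_sites(self):
        s1 = generate_covariates(study_scale(seed=4))
        s2 = generate_covariates(study_scale(seed=4))
        assert s1 == s2


class TestGenerateCommunity:
    def test_saturating_membership(self):
        cfg = co.reduced_scale(seed=2).replace(omega=1 - 1e-12)
        sites = generate_covariates(cfg)
        truth = generate_community(cfg, sites)
        assert (truth.w == 1).all()
        assert (truth.n_true == cfg.pool_size).all()

    def test_flat_community_gives_half_occupancy(self):
        cfg = co.reduced_scale(seed=3).replace(
            sites_per_region=(60, 60, 60),
            pool_size=60,
            omega=1 - 1e-12,
            mu_beta0=0.0,
            sigma_beta0=0.0,
            beta1=0.0,
            mu_beta2=0.0, sigma_beta2=0.0,
            mu_beta3=0.0, sigma_beta3=0.0,
            mu_beta4=0.0, sigma_beta4=0.0,
        )
        sites = generate_covariates(cfg)
        truth = generate_community(cfg, sites)
        assert truth.psi[truth.site_mask[:, None, :].repeat(60, axis=1)].max() == 0.5
        occ = truth.z[:, :, :60].mean()
        assert occ == pytest.approx(0.5, abs=0.02)

    def test_mass_effect_recovered_by_logistic_regression(self):
        # beta1 = 0.76 with all other structure switched off: a plain
        # logistic fit of z on standardized log-mass over 10^4 slots
        # recovers the slope
        import statsmodels.api as sm

        cfg = GeneratorConfig(
            n_regions=1,
            sites_per_region=(2,),
            effort_range=(5, 5),
            pool_size=10_000,
            omega=1 - 1e-12,
            species_range_sd=0.0,
            mu_beta0=0.0, sigma_beta0=0.0,
            beta1=0.76,
            mu_beta2=0.0, sigma_beta2=0.0,
            mu_beta3=0.0, sigma_beta3=0.0,
            mu_beta4=0.0, sigma_beta4=0.0,
            seed=21,
        )
        sites = generate_covariates(cfg)
        truth = generate_community(cfg, sites)
        z = truth.z[0, :, 0]
        # correct for the site-covariate part: slopes are zero, so the
        # only regressor is log-mass
        X = sm.add_constant(truth.logmass_std)
        fit = sm.Logit(z, X).fit(disp=0)
        assert fit.params[1] == pytest.approx(0.76, abs=0.1)


class TestGenerateDetections:
    def test_no_occupancy_no_detections(self):
        cfg = co.reduced_scale(seed=6)
        sites = generate_covariates(cfg)
        truth = generate_community(cfg, sites)
        truth.z[:] = 0
        data = generate_detections(truth, sites, cfg)
        assert all(len(data.species_by_region[r]) == 0 for r in data.regions)

    def test_perfect_detection_saturates_counts(self):
        cfg = co.reduced_scale(seed=6).replace(effort_range=(10, 10))
        sites = generate_covariates(cfg)
        truth = generate_community(cfg, sites)
        truth.z[:, :, :20] = 1
        truth.p[:, :, :20] = 1.0
        data = generate_detections(truth, sites, cfg)
        for r in data.regions:
            np.testing.assert_array_equal(data.y[r], 10)

    def test_per_site_detection_probability_closed_form(self):
        # p = 0.04 per day over 31 occasions: P(detect | occupied) =
        # 1 - 0.96^31 = 0.7179...
        cfg = GeneratorConfig(
            n_regions=1,
            sites_per_region=(2,),
            effort_range=(31, 31),
            pool_size=5_000,
            omega=1 - 1e-12,
            species_range_sd=0.0,
            seed=13,
        )
        sites = generate_covariates(cfg)
        truth = generate_community(cfg, sites)
        truth.z[:, :, :2] = 1
        truth.p[:, :, :2] = 0.04
        rng = np.random.default_rng(99)
        y = rng.binomial(31, truth.z[0, :, :2] * truth.p[0, :, :2])
        freq = (y > 0).mean()
        assert freq == pytest.approx(1 - 0.96**31, abs=0.02)

    def test_detected_richness_monotone_in_effort(self):
        base = co.reduced_scale(seed=8)
        totals = []
        for eff in [(2, 2), (8, 8), (30, 30)]:
            cfg = base.replace(effort_range=eff)
            _, _, data, _ = generate_dataset(cfg)
            totals.append(sum(data.n_species(r) for r in data.regions))
        assert totals == sorted(totals)


class TestPipeline:
    def test_full_determinism(self, tmp_path):
        cfg = co.reduced_scale(seed=17)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        co.write_dataset(cfg, d1)
        co.write_dataset(cfg, d2)
        for name in ["sites.csv", "detections.csv", "traits.csv", "truth.json"]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_respects_invariants(self, reduced_dataset):
        truth = reduced_dataset[2]
        assert (truth.z[truth.w == 0] == 0).all()
        assert ((truth.psi >= 0) & (truth.psi <= 1)).all()
        assert ((truth.p >= 0) & (truth.p <= 1)).all()

    def test_generator_agrees_with_likelihood(self):
        # the observation log-likelihood at the generating detection
        # probabilities beats a +1 SD perturbation, on average over seeds
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = co.reduced_scale(seed=100 + seed)
            sites, truth, data, traits = generate_dataset(cfg)
            sp_index = {sp: k for k, sp in enumerate(truth.species)}
            diffs = 0.0
            for ri, r in enumerate(data.regions):
                s_r = len(data.sites_by_region[r])
                effort = data.effort(r)
                y_pool = np.zeros((cfg.pool_size, s_r), dtype=int)
                for k, sp in enumerate(data.species_by_region[r]):
                    y_pool[sp_index[sp]] = data.y[r][k]
                z = truth.z[ri, :, :s_r]
                p = truth.p[ri, :, :s_r]
                from scipy.special import expit, logit

                p_pert = expit(logit(np.clip(p, 1e-9, 1 - 1e-9)) + cfg.sigma_alpha0)
                diffs += loglik(y_pool, effort, z, p) - loglik(y_pool, effort, z, p_pert)
            if diffs > 0:
                wins += 1
        assert wins >= 0.9 * n_seeds
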