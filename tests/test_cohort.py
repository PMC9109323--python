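"""Synthetic cohort generator and its analytic moment oracle."""

import numpy as np
import pytest

from lcsiq import (
    DGPConfig,
    MODELS,
    coefficients_from_moments,
    emulate_empirical_missingness,
    expected_model_coefficients,
    fiml_moments,
    generate_cohort,
    population_moments,
    table_matched_dataset,
)


class TestDGPConfig:
    def test_defaults_are_the_study_conditions(self, default_config):
        c = default_config
        assert (c.n_bf, c.n_nobf) == (1801, 2763)
        assert (c.mu_true_bf, c.mu_true_nobf) == (103.3, 91.5)
        assert (c.sd_true_bf, c.sd_true_nobf) == (15.1, 12.4)
        assert c.rho_h == c.rho_r == 0.8
        assert (c.obs_mother_mean, c.obs_mother_sd) == (100.0, 15.0)
        assert (c.obs_child_mean, c.obs_child_sd) == (102.8, 11.3)

    @pytest.mark.parametrize("bad", [
        dict(n_bf=0), dict(sd_true_bf=-1.0), dict(rho_h=0.0), dict(rho_r=1.2),
        dict(n_bf=2, moment_matched=True),
    ])
    def test_invalid_configs_raise(self, bad):
        with pytest.raises(ValueError):
            DGPConfig(**bad).validate()

    def test_json_roundtrip(self, tmp_path, default_config):
        p = tmp_path / "dgp.json"
        default_config.to_json(p)
        assert DGPConfig.from_json(p) == default_config


class TestPopulationMoments:
    def test_mixture_mean_and_bf_proportion(self, default_config):
        pm = population_moments(default_config)
        # p*mu1 + (1-p)*mu0 with p = 1801/4564, computed by hand
        assert pm.p_bf == pytest.approx(1801 / 4564)
        p = 1801 / 4564
        assert default_config.pooled_true_mean() == pytest.approx(
            p * 103.3 + (1 - p) * 91.5
        )
        assert default_config.pooled_true_mean() == pytest.approx(96.156, abs=5e-4)
        assert pm.mean[0] == pytest.approx(pm.p_bf)

    def test_moments_match_monte_carlo(self, default_config):
        """Brute-force check: 10^6-dyad stochastic sample reproduces the
        closed-form covariance within Monte-Carlo error."""
        scale = 1_000_000 / default_config.n_total
        big = DGPConfig(
            n_bf=int(1801 * scale), n_nobf=int(2763 * scale),
            moment_matched=False, seed=123,
        )
        x = generate_cohort(big).values
        pm = population_moments(default_config)
        n = x.shape[0]
        np.testing.assert_allclose(x.mean(axis=0), pm.mean, atol=0.08)
        sample_cov = np.cov(x, rowvar=False, bias=True)
        # entry-wise ~4 MC standard errors (largest entries are O(200))
        np.testing.assert_allclose(sample_cov, pm.cov, atol=4 * 225 * np.sqrt(2 / n))
        # Cov(BF, M_true-scale check): p(1-p)(mu1-mu0) on the BF/observed path
        p = pm.p_bf
        cov_b_ztrue = p * (1 - p) * (103.3 - 91.5) / np.sqrt(default_config.pooled_true_var())
        assert pm.cov[0, 1] == pytest.approx(15.0 * 0.8 * cov_b_ztrue)

    def test_var_bf_is_bernoulli_variance(self, default_config):
        pm = population_moments(default_config)
        assert pm.cov[0, 0] == pytest.approx(pm.p_bf * (1 - pm.p_bf))

    def test_no_noise_limit_collapses_child_onto_mother(self):
        """rho_h = rho_r = 1 with equal group means: C_obs is an exact affine
        function of M_obs, so the conditional covariance structure vanishes."""
        cfg = DGPConfig(rho_h=1.0, rho_r=1.0, mu_true_bf=100.0, mu_true_nobf=100.0,
                        sd_true_bf=15.0, sd_true_nobf=15.0)
        pm = population_moments(cfg)
        r = pm.cov[1, 2] / np.sqrt(pm.cov[1, 1] * pm.cov[2, 2])
        assert r == pytest.approx(1.0, abs=1e-12)
        resid = pm.cov[2, 2] - pm.cov[1, 2] ** 2 / pm.cov[1, 1]
        assert resid == pytest.approx(0.0, abs=1e-9)


class TestGenerateCohort:
    def test_group_sizes_and_determinism(self, default_config, matched_cohort):
        x = matched_cohort.values
        assert matched_cohort.n_total == 4564
        assert int(x[:, 0].sum()) == 1801
        again = generate_cohort(default_config)
        np.testing.assert_array_equal(again.values, x)

    def test_moment_matched_sample_moments_are_exact(self, default_config, matched_cohort):
        x = matched_cohort.values
        assert x[:, 1].mean() == pytest.approx(100.0, abs=1e-9)
        assert x[:, 1].std() == pytest.approx(15.0, abs=1e-9)
        assert x[:, 2].mean() == pytest.approx(102.8, abs=1e-9)
        assert x[:, 2].std() == pytest.approx(11.3, abs=1e-9)
        pm = population_moments(default_config)
        np.testing.assert_allclose(
            np.cov(x, rowvar=False, bias=True), pm.cov, atol=1e-9
        )

    def test_moment_matched_latent_moments_are_exact(self, default_config):
        ds, latent = generate_cohort(default_config, return_latent=True)
        bf = ds.values[:, 0].astype(bool)
        tm = latent["true_mother"].to_numpy()
        tc = latent["true_child"].to_numpy()
        assert tm[bf].mean() == pytest.approx(103.3, abs=1e-9)
        assert tm[bf].std() == pytest.approx(15.1, abs=1e-9)
        assert tm[~bf].mean() == pytest.approx(91.5, abs=1e-9)
        assert tm[~bf].std() == pytest.approx(12.4, abs=1e-9)
        assert np.corrcoef(tc, tm)[0, 1] == pytest.approx(0.8, abs=1e-9)
        assert np.corrcoef(ds.values[:, 1], tm)[0, 1] == pytest.approx(0.8, abs=1e-9)
        assert np.corrcoef(ds.values[:, 2], tc)[0, 1] == pytest.approx(0.8, abs=1e-9)

    def test_perfect_reliability_limit(self):
        cfg = DGPConfig(n_bf=50, n_nobf=70, rho_r=1.0, seed=3)
        ds, latent = generate_cohort(cfg, return_latent=True)
        r = np.corrcoef(ds.values[:, 1], latent["true_mother"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_stochastic_moments_converge(self, default_config):
        """At the default n, stochastic sample moments sit within ~4 MC
        standard errors of the population moments (averaged over seeds)."""
        pm = population_moments(default_config)
        devs = []
        for seed in range(20):
            cfg = DGPConfig(moment_matched=False, seed=seed)
            x = generate_cohort(cfg).values
            devs.append(x.mean(axis=0) - pm.mean)
        mean_dev = np.abs(np.mean(devs, axis=0))
        se = np.sqrt(np.diag(pm.cov) / (default_config.n_total * 20))
        assert (mean_dev < 4 * se).all()

    def test_child_true_prescale_is_immaterial(self, default_config):
        """The observed-scale rescale absorbs the child true-score
        location/scale, so the fitted BF coefficients are invariant to it."""
        alt = DGPConfig(child_true_mean=0.0, child_true_sd=1.0)
        base = generate_cohort(default_config)
        varied = generate_cohort(alt)
        for model in MODELS:
            f0 = coefficients_from_moments(fiml_moments(base)[0], model)
            f1 = coefficients_from_moments(fiml_moments(varied)[0], model)
            assert f1.bf_effect == pytest.approx(f0.bf_effect, abs=1e-9)


class TestExpectedModelCoefficients:
    def test_default_sign_pattern(self, default_config):
        assert expected_model_coefficients(default_config, "forward_adj").bf_effect > 0
        assert expected_model_coefficients(default_config, "backward_adj").bf_effect > 0
        assert expected_model_coefficients(default_config, "forward_noadj").bf_effect < 0

    @pytest.mark.parametrize("rho", [0.7, 0.9])
    def test_sign_pattern_robust_to_heritability(self, rho):
        cfg = DGPConfig(rho_h=rho)
        signs = [
            np.sign(expected_model_coefficients(cfg, m).bf_effect) for m in MODELS
        ]
        assert signs == [1, 1, -1]

    def test_single_group_raises(self):
        cfg = DGPConfig(n_bf=4564, n_nobf=1)
        cfg.n_nobf = 0  # bypass count validation to hit the Var(BF) guard
        with pytest.raises(ValueError):
            expected_model_coefficients(cfg, "forward_adj")


class TestEmulateEmpiricalMissingness:
    def test_targets_equal_n_leaves_dataset_unchanged(self, small_cohort):
        out = emulate_empirical_missingness(
            small_cohort, {"bf": 600, "iq_mother": 600, "iq_child": 600}, seed=1
        )
        np.testing.assert_array_equal(out.values, small_cohort.values)

    def test_empirical_target_counts_hit_exactly(self):
        cfg = DGPConfig(n_bf=2436, n_nobf=3736, moment_matched=False, seed=9)
        cohort = generate_cohort(cfg)  # 6172 records, the first-child analysis n
        targets = {"iq_mother": 5939, "iq_child": 3950, "bf": 4564}
        masked = emulate_empirical_missingness(cohort, targets, seed=2)
        assert masked.observed_counts() == targets
        assert not np.isnan(masked.values).all(axis=1).any()

    def test_different_seeds_same_counts_different_pattern(self, small_cohort):
        targets = {"bf": 500, "iq_mother": 450, "iq_child": 400}
        a = emulate_empirical_missingness(small_cohort, targets, seed=1)
        b = emulate_empirical_missingness(small_cohort, targets, seed=2)
        assert a.observed_counts() == b.observed_counts() == targets
        assert not np.array_equal(np.isnan(a.values), np.isnan(b.values))

    def test_infeasible_target_raises(self, small_cohort):
        with pytest.raises(ValueError, match="target"):
            emulate_empirical_missingness(small_cohort, {"bf": 601}, seed=1)


class TestTableMatchedDataset:
    def test_moments_match_requested_table(self):
        ds = table_matched_dataset(
            n=500, p_bf=0.39, mean_mother=100.0, sd_mother=15.0,
            mean_child=102.8, sd_child=11.3,
            r_mother_child=0.506, r_mother_bf=0.385, r_child_bf=0.288, seed=4,
        )
        x = ds.values
        p = round(500 * 0.39) / 500
        assert x[:, 0].mean() == pytest.approx(p, abs=1e-12)
        assert x[:, 1].mean() == pytest.approx(100.0, abs=1e-9)
        assert x[:, 1].std() == pytest.approx(15.0, abs=1e-9)
        corr = np.corrcoef(x, rowvar=False)
        assert corr[1, 2] == pytest.approx(0.506, abs=1e-9)
        assert corr[0, 1] == pytest.approx(0.385, abs=1e-9)
        assert corr[0, 2] == pytest.approx(0.288, abs=1e-9)
        assert set(np.unique(x[:, 0])) == {0.0, 1.0}
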