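import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smrmap.shrinkage import (
    PoissonGammaModel,
    SamplerSettings,
    log_posterior,
    sample_posterior,
    shrink_smr,
)


def region_table(d, e):
    return pd.DataFrame({"region_id": [f"r{i}" for i in range(len(d))],
                         "tier": "unit", "deaths": d, "expected": e})


class TestLogPosterior:
    def test_matches_density_composition(self):
        # independent oracle: compose scipy's Poisson pmf and Gamma/Exp pdfs
        d, e, th, a, b = [4.0], [5.0], [0.8], 2.0, 0.5
        oracle = (stats.poisson.logpmf(4, 5 * 0.8)
                  + stats.gamma.logpdf(0.8, a, scale=b)
                  + stats.expon.logpdf(a)
                  + stats.gamma.logpdf(b, 0.1, scale=1.0))
        assert log_posterior(d, e, th, a, b) == pytest.approx(oracle, abs=1e-10)

    def test_vanishing_likelihood_leaves_priors(self):
        # d = 0, e = 0: the data term contributes exactly zero
        a, b = 1.5, 0.7
        val = log_posterior([0.0], [0.0], [1.2], a, b)
        priors = (stats.gamma.logpdf(1.2, a, scale=b) + stats.expon.logpdf(a)
                  + stats.gamma.logpdf(b, 0.1, scale=1.0))
        assert val == pytest.approx(priors, abs=1e-10)

    def test_additivity_under_duplication(self):
        d, e, th = [3.0, 0.0], [2.0, 1.0], [1.1, 0.4]
        a, b = 2.0, 0.5
        single = log_posterior(d, e, th, a, b)
        double = log_posterior(d * 2, e * 2, th * 2, a, b)
        hyper = stats.expon.logpdf(a) + stats.gamma.logpdf(b, 0.1, scale=1.0)
        assert double - hyper == pytest.approx(2 * (single - hyper), rel=1e-12)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            log_posterior([1.0], [1.0], [0.0], 1.0, 1.0)


class TestConjugateOracle:
    def test_fixed_hyperparameters_match_closed_form(self):
        # theta | d=4, e=5, alpha=2, beta=0.5 is Gamma(6, rate 7)
        post = sample_posterior(region_table([4], [5.0]),
                                SamplerSettings(fixed_alpha=2.0, fixed_beta=0.5,
                                                seed=10),
                                compute_diagnostics=False)
        draws = post.theta_draws.ravel()
        mean_exact, var_exact = 6 / 7, 6 / 49
        se_mean = np.sqrt(var_exact / draws.size)  # draws are iid here
        assert abs(draws.mean() - mean_exact) < 3 * se_mean
        # central 4th moment of Gamma(shape k) is (3 + 6/k) var^2, so the
        # sampling variance of the sample variance is ~ (m4 - var^2)/N
        se_var = np.sqrt((3 + 6 / 6 - 1) * var_exact ** 2 / draws.size)
        assert abs(draws.var() - var_exact) < 3 * se_var

    def test_prior_recovery_with_no_data(self):
        post = sample_posterior(region_table([0], [0.0]),
                                SamplerSettings(fixed_alpha=1.0, fixed_beta=1.0,
                                                seed=2),
                                compute_diagnostics=False)
        draws = post.theta_draws.ravel()
        assert abs(draws.mean() - 1.0) < 3 / np.sqrt(draws.size)


class TestSampler:
    def test_seed_determinism(self):
        tbl = region_table([4, 0, 9], [5.0, 1.0, 7.5])
        s = SamplerSettings(chains=2, iters=400, warmup=200, seed=7)
        p1 = sample_posterior(tbl, s, compute_diagnostics=False)
        p2 = sample_posterior(tbl, s, compute_diagnostics=False)
        np.testing.assert_array_equal(p1.theta_draws, p2.theta_draws)
        np.testing.assert_array_equal(p1.alpha_draws, p2.alpha_draws)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="at least one region"):
            sample_posterior(region_table([], []), SamplerSettings())

    def test_acceptance_rates_in_band(self, small_study):
        from smrmap.standardization import make_region_table

        counts, rates = small_study.slices["all"]
        tbl = make_region_table(counts, rates)
        post = sample_posterior(tbl, SamplerSettings(chains=2, iters=1000,
                                                     warmup=500, seed=3),
                                compute_diagnostics=False)
        assert 0.15 < post.accept_alpha < 0.6
        assert 0.15 < post.accept_beta < 0.6

    def test_rhat_reported_for_all_parameters(self):
        tbl = region_table([4, 7], [5.0, 6.0])
        post = sample_posterior(tbl, SamplerSettings(chains=2, iters=600,
                                                     warmup=300, seed=1))
        assert {"alpha", "beta", "theta[r0]", "theta[r1]"} <= set(post.rhat)

    def test_parameter_recovery_on_simulated_data(self):
        # 1,000 regions, alpha_true = 10, beta_true = 0.1, independent risks
        from smrmap.standardization import make_region_table
        from smrmap.synthetic import SimulationConfig, simulate_study

        cfg = SimulationConfig(grid_shape=(25, 40), n_middle=100, n_top=25,
                               theta_shape=10.0, theta_scale=0.1, seed=21)
        study = simulate_study(cfg)
        counts, rates = study.slices["all"]
        tbl = make_region_table(counts, rates)
        post = sample_posterior(tbl, SamplerSettings(chains=2, iters=1500,
                                                     warmup=750, seed=22),
                                compute_diagnostics=False)
        assert abs(post.alpha_mean - 10.0) / 10.0 < 0.30
        assert abs(post.alpha_mean * post.beta_mean - 1.0) < 0.05


class TestShrinkage:
    def test_data_dominated_limit(self):
        # enormous expected deaths with d = e: shrunk SMR pinned at 100
        tbl = region_table([1_000_000, 50], [1_000_000.0, 60.0])
        post = sample_posterior(tbl, SamplerSettings(seed=4),
                                compute_diagnostics=False)
        smr = shrink_smr(post, check_convergence=False)
        assert smr.loc["r0"] == pytest.approx(100.0, abs=1.0)

    def test_small_e_region_pulled_toward_ensemble(self):
        # raw SMR 3000 on e = 0.1 must shrink drastically toward the
        # cross-region mean; conjugate mean at the posterior hyperparameters
        # is the quantitative oracle
        d = [3] + [10] * 30
        e = [0.1] + [10.0] * 30
        post = sample_posterior(region_table(d, e),
                                SamplerSettings(seed=5), compute_diagnostics=False)
        smr = shrink_smr(post, check_convergence=False)
        raw0 = 100 * 3 / 0.1
        assert smr.loc["r0"] < raw0 / 3
        a, b = post.alpha_mean, post.beta_mean
        conj = 100 * (a + 3) / (1 / b + 0.1)
        assert smr.loc["r0"] == pytest.approx(conj, rel=0.15)

    def test_exchangeable_regions_shrink_identically(self):
        d = [5, 5, 20, 1]
        e = [4.0, 4.0, 18.0, 2.0]
        post = sample_posterior(region_table(d, e), SamplerSettings(seed=6),
                                compute_diagnostics=False)
        smr = shrink_smr(post, check_convergence=False)
        flat = post.theta_draws.reshape(-1, 4)
        mc_se = 100 * np.sqrt(flat[:, 0].var() / flat.shape[0]
                              + flat[:, 1].var() / flat.shape[0])
        # identical (d, e) regions: equal posterior means up to MC error;
        # draws autocorrelate so allow a generous multiple
        assert abs(smr.loc["r0"] - smr.loc["r1"]) < 10 * mc_se

    def test_shrunk_sd_not_above_raw_sd(self, small_study):
        from smrmap.standardization import make_region_table

        counts, rates = small_study.slices["all"]
        tbl = make_region_table(counts, rates)
        post = sample_posterior(tbl, SamplerSettings(chains=2, iters=1000,
                                                     warmup=500, seed=8),
                                compute_diagnostics=False)
        smr = shrink_smr(post, check_convergence=False)
        assert smr.std() <= tbl["raw_smr"].std()

    def test_smaller_e_shrinks_more_at_equal_raw_smr(self):
        # matched pair: same raw SMR (150), expected deaths 2 vs 200
        d = [3, 300] + [10] * 20
        e = [2.0, 200.0] + [10.0] * 20
        post = sample_posterior(region_table(d, e), SamplerSettings(seed=9),
                                compute_diagnostics=False)
        smr = shrink_smr(post, check_convergence=False)
        shrink_small = abs(smr.loc["r0"] - 150.0)
        shrink_large = abs(smr.loc["r1"] - 150.0)
        assert shrink_small > shrink_large


class TestModelFrontEnd:
    def test_fit_and_summary(self):
        tbl = region_table([4, 9], [5.0, 7.0])
        model = PoissonGammaModel(chains=2, iters=600, warmup=300, seed=11)
        model.fit(tbl)
        summ = model.summary()
        assert list(summ["region_id"]) == ["r0", "r1"]
        assert (summ["ci_low"] <= summ["shrunk_smr"]).all()
        assert (summ["shrunk_smr"] <= summ["ci_high"]).all()
        np.testing.assert_allclose(model.shrunk_smr_.to_numpy(),
                                   summ["shrunk_smr"].to_numpy())
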