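"""Bayesian GLMM machinery: log posterior, sampling, intervals, checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from martendyn import (
    AbundanceModelSpec,
    GrowthModelSpec,
    credible_interval,
    fit,
    log_posterior,
    posterior_predictive_check,
)
from martendyn.glmm import parameter_names

from conftest import make_abundance_frame

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


class TestLogPosterior:
    def test_single_datum_matches_hand_computed_sum(self):
        # known sigma = 1, no covariates, no random effects, datum R = 0:
        # log posterior = logN(0 | 0, 1) + logN(beta0=0 | 0, 2)
        spec = GrowthModelSpec(covariates=(), group_col=None, known_sigma=1.0)
        data = pd.DataFrame({"growth_rate": [0.0]})
        expected = (-_HALF_LOG_2PI) + (-_HALF_LOG_2PI - np.log(2.0))
        assert log_posterior(spec, np.array([0.0]), data) == pytest.approx(expected)

    def test_duplicate_row_adds_exactly_its_likelihood(self):
        spec = GrowthModelSpec(covariates=("z",), group_col=None, known_sigma=0.7)
        one = pd.DataFrame({"growth_rate": [0.3], "z": [1.2]})
        two = pd.concat([one, one], ignore_index=True)
        params = np.array([0.1, -0.2])
        lp1 = log_posterior(spec, params, one)
        lp2 = log_posterior(spec, params, two)
        mu = 0.1 + (-0.2) * 1.2
        row_ll = stats.norm.logpdf(0.3, mu, 0.7)
        assert lp2 - lp1 == pytest.approx(row_ll)

    def test_nonfinite_parameter_gives_minus_inf(self):
        spec = GrowthModelSpec(covariates=(), group_col=None, known_sigma=1.0)
        data = pd.DataFrame({"growth_rate": [0.0]})
        assert log_posterior(spec, np.array([np.inf]), data) == -np.inf

    def test_missing_covariate_rejected(self):
        spec = AbundanceModelSpec()
        data = pd.DataFrame({"tracks": [1], "year": [2007]})
        with pytest.raises(ValueError, match="missing columns"):
            log_posterior(spec, np.zeros(3), data)

    def test_negative_counts_rejected(self):
        spec = AbundanceModelSpec(covariates=(), year_col=None)
        data = pd.DataFrame(
            {"tracks": [-1], "length_km": [2.0], "days_since_snow": [3.0]}
        )
        with pytest.raises(ValueError, match="non-negative"):
            log_posterior(spec, np.zeros(2), data)

    def test_parameter_layout_names(self):
        spec = GrowthModelSpec()
        data = pd.DataFrame(
            {
                "growth_rate": np.random.default_rng(0).normal(size=6),
                "rodent_index": np.random.default_rng(1).normal(size=6),
                "elevation": np.random.default_rng(2).normal(size=6),
                "rodent_x_elevation": np.random.default_rng(4).normal(size=6),
                "snow": np.random.default_rng(3).normal(size=6),
                "group_id": ["a", "a", "b", "b", "c", "c"],
            }
        )
        names = parameter_names(spec, data)
        assert names[0] == "beta_intercept"
        assert "u[a]" in names and "log_sigma_group" in names and "log_sigma" in names


class TestFit:
    def test_conjugate_normal_posterior_mean(self):
        # known sigma, intercept-only, prior N(0, 2^2): closed-form posterior
        rng = np.random.default_rng(5)
        sigma = 1.0
        y = rng.normal(0.8, sigma, 60)
        data = pd.DataFrame({"growth_rate": y})
        spec = GrowthModelSpec(covariates=(), group_col=None, known_sigma=sigma)
        post = fit(spec, data, chains=2, iterations=2000, warmup=1000, seed=0)
        prec = len(y) / sigma**2 + 1.0 / 4.0
        closed_mean = (y.sum() / sigma**2) / prec
        closed_sd = 1.0 / np.sqrt(prec)
        mc_se = closed_sd / np.sqrt(post.ess_bulk["beta_intercept"])
        assert abs(post.mean["beta_intercept"] - closed_mean) < 3 * max(mc_se, 1e-3)

    def test_independent_chains_converge(self):
        df, _ = make_abundance_frame(1000, [-1.0, 0.3, 0.2, 0.0, 0.1, 0.2, -0.1],
                                     theta=2.0, year_sd=0.2, seed=3)
        post = fit(AbundanceModelSpec(), df, chains=2, iterations=4000, warmup=2000, seed=4)
        assert post.converged
        assert (post.rhat < 1.01).all()
        assert (post.ess_bulk > 400).all()

    def test_identical_seed_identical_draws(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame({"growth_rate": rng.normal(size=40)})
        spec = GrowthModelSpec(covariates=(), group_col=None)
        a = fit(spec, data, chains=2, iterations=600, warmup=300, seed=9)
        b = fit(spec, data, chains=2, iterations=600, warmup=300, seed=9)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_only_sampling_recovers_slope_prior(self):
        # with the likelihood switched off, slope marginals are Normal(0, 2)
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"growth_rate": rng.normal(size=30), "z": rng.normal(size=30)})
        spec = GrowthModelSpec(covariates=("z",), group_col=None, known_sigma=1.0)
        post = fit(spec, data, chains=2, iterations=6000, warmup=1000, seed=2,
                   prior_only=True)
        draws = post.flat[:, post.names.index("beta_z")]
        ks = stats.kstest(draws, stats.norm(0, 2).cdf).statistic
        assert ks < 0.05

    def test_standardization_contract(self):
        # slopes fitted on z-scores map exactly to raw-scale slopes via the
        # standardization constants (posterior means, tolerance 0.02)
        rng = np.random.default_rng(8)
        n = 500
        raw = rng.normal(10.0, 3.0, n)
        y = 0.5 + 0.25 * (raw - raw.mean()) / raw.std(ddof=1) + rng.normal(0, 0.3, n)
        mean, sd = raw.mean(), raw.std(ddof=1)
        spec = GrowthModelSpec(covariates=("x",), group_col=None)
        post_z = fit(spec, pd.DataFrame({"growth_rate": y, "x": (raw - mean) / sd}),
                     chains=2, iterations=1500, warmup=750, seed=1)
        post_raw = fit(spec, pd.DataFrame({"growth_rate": y, "x": raw}),
                       chains=2, iterations=1500, warmup=750, seed=1)
        slope_z = post_z.mean["beta_x"]
        slope_raw = post_raw.mean["beta_x"]
        assert slope_raw * sd == pytest.approx(slope_z, abs=0.02)
        intercept_from_raw = post_raw.mean["beta_intercept"] + slope_raw * mean
        assert intercept_from_raw == pytest.approx(post_z.mean["beta_intercept"], abs=0.02)


class TestCredibleInterval:
    def test_standard_normal_80pct(self):
        rng = np.random.default_rng(0)
        lo, hi, excl = credible_interval(rng.standard_normal(10**6), level=0.80)
        assert lo == pytest.approx(-1.2816, abs=0.01)
        assert hi == pytest.approx(1.2816, abs=0.01)
        assert not excl

    def test_constant_draws(self):
        lo, hi, excl = credible_interval(np.full(200, 3.5))
        assert lo == hi == 3.5
        assert excl

    def test_level_one_gives_range(self):
        draws = np.array([1.0, 5.0] + [2.0] * 198)
        lo, hi, _ = credible_interval(draws, level=1.0)
        assert lo == 1.0 and hi == 5.0

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            credible_interval(np.ones(50))


class TestPosteriorPredictiveCheck:
    @pytest.fixture(scope="class")
    def fitted(self):
        df, _ = make_abundance_frame(1000, [-1.0, 0.3, 0.2, 0.0, 0.1, 0.2, -0.1],
                                     theta=2.0, year_sd=0.15, seed=11)
        post = fit(AbundanceModelSpec(), df, chains=2, iterations=2000, warmup=1000, seed=12)
        return df, post

    def test_self_simulated_data_is_calibrated(self, fitted):
        df, post = fitted
        ppc = posterior_predictive_check(AbundanceModelSpec(), post, df, seed=0)
        assert set(ppc["statistic"]) == {"mean", "sd", "prop_zero"}
        assert ((ppc["observed_quantile"] > 0.01) & (ppc["observed_quantile"] < 0.99)).all()

    def test_zero_proportion_zero_when_no_zeros(self, fitted):
        df, post = fitted
        df2 = df.copy()
        df2["tracks"] = df2["tracks"] + 1
        ppc = posterior_predictive_check(AbundanceModelSpec(), post, df2, seed=0)
        row = ppc.set_index("statistic").loc["prop_zero"]
        assert row["observed"] == 0.0

    def test_replicate_mean_tracks_data_mean(self, fitted):
        df, post = fitted
        ppc = posterior_predictive_check(AbundanceModelSpec(), post, df, seed=1)
        row = ppc.set_index("statistic").loc["mean"]
        assert row["rep_mean"] == pytest.approx(row["observed"], rel=0.15)
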