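"""Priors, posterior, MLE, MCMC sampling and convergence diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

import sinesurv as sv
from sinesurv.bayes import McmcConfig, sample_unconstrained
from sinesurv.diagnostics import ess, mcse, rhat


class TestPriors:
    def test_gamma_logpdf_matches_scipy(self):
        pc = sv.PriorConfig()
        # weibull-family parameter vector (lam, alpha), no coefficients
        lp = sv.log_prior([1.0, 1.0], pc, has_shape=True, n_coef=0)
        expected = 2 * gamma_dist.logpdf(1.0, a=10, scale=0.1)
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_normal_coefficient_prior(self):
        pc = sv.PriorConfig()
        lp = sv.log_prior([1.0, 0.0], pc, has_shape=False, n_coef=1)
        beta_part = lp - gamma_dist.logpdf(1.0, a=10, scale=0.1)
        assert beta_part == pytest.approx(-math.log(10 * math.sqrt(2 * math.pi)), abs=1e-10)
        assert beta_part == pytest.approx(norm.logpdf(0, 0, 10), abs=1e-12)

    def test_out_of_domain_gives_minus_infinity(self):
        pc = sv.PriorConfig()
        assert sv.log_prior([-1.0, 1.0], pc, has_shape=True, n_coef=0) == -np.inf
        assert sv.log_prior([1.0, 0.0], pc, has_shape=True, n_coef=0) == -np.inf

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            sv.PriorConfig(a1=-1.0)
        with pytest.raises(ValueError):
            sv.PriorConfig(beta_sd=0.0)


class TestLogPosterior:
    def test_decomposes_into_likelihood_plus_prior(self, toy_dataset):
        model = sv.SineGPH.from_dataset(toy_dataset, family="weibull")
        pc = sv.PriorConfig()
        params = np.array([0.5, 1.2, -0.3])
        lp = sv.log_posterior(params, model, pc)
        expected = model.loglike(params) + sv.log_prior(params, pc, True, 1)
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_empty_data_reduces_to_prior(self):
        model = sv.SineGPH(time=[], event=[], family="weibull")
        pc = sv.PriorConfig()
        params = np.array([0.8, 1.1])
        assert sv.log_posterior(params, model, pc) == pytest.approx(
            sv.log_prior(params, pc, True, 0), abs=1e-12
        )

    def test_data_duplication_doubles_likelihood_part(self, toy_dataset):
        pc = sv.PriorConfig()
        params = np.array([0.5, 1.2, -0.3])
        m1 = sv.SineGPH.from_dataset(toy_dataset, family="weibull")
        doubled = sv.SurvivalDataset(
            time=np.tile(toy_dataset.time, 2),
            event=np.tile(toy_dataset.event, 2),
            covariates=np.tile(toy_dataset.covariates, (2, 1)),
            covariate_names=toy_dataset.covariate_names,
        )
        m2 = sv.SineGPH.from_dataset(doubled, family="weibull")
        like1 = sv.log_posterior(params, m1, pc) - sv.log_prior(params, pc, True, 1)
        like2 = sv.log_posterior(params, m2, pc) - sv.log_prior(params, pc, True, 1)
        assert like2 == pytest.approx(2 * like1, rel=1e-10)


class TestMLE:
    def test_sine_exponential_matches_grid_search(self):
        """1-D grid-search oracle for the i.i.d. sine-exponential MLE."""
        rng = np.random.default_rng(8)
        t = sv.make_sine("exponential", 0.7).ppf(rng.uniform(0, 0.999, 300))
        model = sv.SineGPH(time=t, event=np.ones(t.size), family="exponential")
        res = model.fit()
        assert res.converged
        grid = np.linspace(0.3, 1.5, 4001)
        lls = [model.loglike([g]) for g in grid]
        lam_grid = grid[int(np.argmax(lls))]
        assert res.params[0] == pytest.approx(lam_grid, abs=1e-3)
        assert res.grad_norm < 1e-5 * max(1.0, abs(res.llf))

    def test_parameter_recovery_sw_ph(self):
        """n=1000 SW-PH simulation: estimates within 3 SEs of the truth."""
        truth = {"lam": 0.34, "alpha": 0.95, "beta": -0.06}
        d = sv.make_sine("weibull", truth["lam"], truth["alpha"])
        cfg = sv.SimulationConfig(
            dist=d, beta=[truth["beta"]], n=1000, covariates="bernoulli",
            censoring=("uniform", 12.0), seed=314,
        )
        ds, _ = sv.simulate_dataset(cfg)
        model = sv.SineGPH(ds.time, ds.event, exog=ds.covariates, family="weibull")
        res = model.fit()
        assert res.converged
        se = res.bse
        assert np.all(np.isfinite(se))
        target = np.array([truth["lam"], truth["alpha"], truth["beta"]])
        assert np.all(np.abs(res.params - target) < 3 * se)

    def test_restart_at_optimum_is_stationary(self, toy_dataset):
        model = sv.SineGPH.from_dataset(toy_dataset, family="lomax")
        first = model.fit()
        second = model.fit(start=first.params)
        assert second.llf == pytest.approx(first.llf, abs=1e-6)
        assert np.allclose(second.params, first.params, rtol=1e-3)

    def test_summary_table_columns(self, toy_dataset):
        res = sv.SineGPH.from_dataset(toy_dataset, family="weibull").fit()
        table = res.summary()
        assert list(table.columns) == ["Estimate", "SE", "2.5%", "97.5%"]
        assert list(table.index) == ["lam", "alpha", "beta_treatment"]


class TestDiagnostics:
    def test_identical_chains_rhat_one(self):
        # identical stationary chains carry no between-chain signal
        x = np.random.default_rng(9).standard_normal(500)
        chains = np.tile(x, (4, 1))
        assert rhat(chains) == pytest.approx(1.0, abs=1e-2)

    def test_disjoint_chains_rhat_large(self):
        chains = np.vstack([np.zeros(200) + np.linspace(0, 0.01, 200), 10 + np.linspace(0, 0.01, 200)])
        assert rhat(chains) > 1.1

    def test_iid_normal_rhat_near_one_vs_arviz(self):
        az = pytest.importorskip("arviz")
        draws = np.random.default_rng(10).standard_normal((4, 1000))
        r = rhat(draws)
        assert 0.999 <= r <= 1.01
        ref = float(np.asarray(az.rhat(az.convert_to_dataset(draws[:, :, None]))["x"].values).ravel()[0])
        assert r == pytest.approx(ref, abs=5e-3)

    def test_iid_ess_near_total(self):
        az = pytest.importorskip("arviz")
        draws = np.random.default_rng(11).standard_normal((4, 1000))
        n_eff = ess(draws)
        assert abs(n_eff - 4000) / 4000 < 0.2
        ref = float(np.asarray(az.ess(az.convert_to_dataset(draws[:, :, None]))["x"].values).ravel()[0])
        assert abs(n_eff - ref) / ref < 0.15

    def test_ar1_ess_matches_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(12)
        chains = np.empty((4, 4000))
        for c in range(4):
            e = rng.standard_normal(4000)
            x = np.empty(4000)
            x[0] = e[0]
            for i in range(1, 4000):
                x[i] = rho * x[i - 1] + math.sqrt(1 - rho**2) * e[i]
            chains[c] = x
        efficiency = ess(chains) / chains.size
        limit = (1 - rho) / (1 + rho)  # iid-equivalent fraction for AR(1)
        assert limit / 2 < efficiency < limit * 2

    def test_constant_chain_degenerate(self):
        chains = np.full((4, 100), 3.14)
        assert ess(chains) == 0.0
        assert math.isnan(rhat(chains))

    def test_mcse_is_sd_over_sqrt_ess(self):
        draws = np.random.default_rng(13).standard_normal((4, 500))
        assert mcse(draws) == pytest.approx(draws.std(ddof=1) / math.sqrt(ess(draws)), rel=1e-10)


class TestSamplers:
    def test_standard_normal_target_hmc(self):
        logp = lambda z: float(-0.5 * np.sum(z**2))
        cfg = McmcConfig(chains=4, iterations=1000, warmup=500, seed=5)
        inits = np.random.default_rng(0).normal(size=(4, 2))
        draws, ndiv, acc = sample_unconstrained(logp, 2, cfg, inits)
        x = draws[:, :, 0]
        assert abs(x.mean()) < 3 * mcse(x)
        assert abs(x.std() - 1.0) < 0.05
        assert ndiv.sum() == 0

    def test_standard_normal_target_adaptive_metropolis(self):
        logp = lambda z: float(-0.5 * np.sum(z**2))
        cfg = McmcConfig(
            chains=4, iterations=3000, warmup=1000, seed=6, sampler="adaptive_metropolis"
        )
        inits = np.random.default_rng(1).normal(size=(4, 2))
        draws, _, acc = sample_unconstrained(logp, 2, cfg, inits)
        x = draws[:, :, 0]
        assert abs(x.mean()) < 4 * mcse(x)
        assert abs(x.std() - 1.0) < 0.1
        assert 0.1 < acc.mean() < 0.6

    def test_prior_recovery_with_no_data(self):
        """With n=0 the posterior is the Gamma(10,10) prior: mean 1, sd 0.316."""
        model = sv.SineGPH(time=[], event=[], family="weibull")
        res = model.fit_bayes(
            mcmc=sv.McmcConfig(chains=4, iterations=1000, warmup=500, seed=7)
        )
        s = res.summary()
        for p in ("lam", "alpha"):
            assert abs(s.loc[p, "Estimate"] - 1.0) < 3 * s.loc[p, "SE"] + 1e-9
            assert abs(s.loc[p, "SD"] - math.sqrt(10) / 10) < 0.03

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, warmup=100)
        with pytest.raises(ValueError):
            McmcConfig(sampler="nuts")


class TestGastricLikeFit:
    def test_convergence_contract(self, gastric_fit):
        """Rhat <= 1.01, ESS > 400 and MCSE < 5% of sd on the synthetic trial."""
        _, _, res = gastric_fit
        s = res.summary()
        assert (s["Rhat"] <= 1.01).all()
        assert (s["N_eff"] > 400).all()
        assert (s["SE"] < 0.05 * s["SD"]).all()
        assert res.diagnostics_ok()

    def test_posterior_draws_positive_and_finite(self, gastric_fit):
        _, _, res = gastric_fit
        draws = res.samples.draws
        assert np.all(np.isfinite(draws))
        assert np.all(draws[:, :, :2] > 0)  # lam, alpha on the natural scale

    def test_posterior_covers_truth(self, gastric_fit):
        _, truth, res = gastric_fit
        s = res.summary()
        # generous 99.9%-style check: truth within ~4 posterior sd of the mean
        for name, val in (("lam", truth["lam"]), ("alpha", truth["alpha"]),
                          ("beta_treatment", truth["beta"][0])):
            assert abs(s.loc[name, "Estimate"] - val) < 4 * s.loc[name, "SD"]

    def test_summary_has_table_schema(self, gastric_fit):
        _, _, res = gastric_fit
        assert list(res.summary().columns) == [
            "Estimate", "SE", "SD", "2.5%", "Medium", "97.5%", "N_eff", "Rhat",
        ]

    def test_quantiles_monotone(self, gastric_fit):
        _, _, res = gastric_fit
        s = res.summary()
        assert (s["2.5%"] <= s["Medium"]).all() and (s["Medium"] <= s["97.5%"]).all()
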