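"""Poisson-lognormal model: densities, quadrature, Gibbs steps, sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cancerineq import (
    CountTable,
    MCMCConfig,
    ModelSpec,
    encode_design,
    fit_mcmc,
    log_joint,
    marginal_loglik,
    marginal_moments,
)
from cancerineq.age_bands import AgeBandScheme
from cancerineq.model import (
    BETA_PRIOR_VAR,
    PosteriorDraws,
    beta_conditional,
    draw_beta,
    draw_sigma2,
    poisson_loglik,
)
from cancerineq.synthetic import default_scenario, generate_scenario, simulate_counts


def tiny_table(counts, exposures):
    scheme = AgeBandScheme.five_year(45, 45)  # bands 45-49, 50+
    rows = []
    for i, (c, e) in enumerate(zip(counts, exposures)):
        rows.append({"age_band": "45-49", "year": 2001 + i, "gender": "male",
                     "decile": 1, "region": "N", "count": c, "exposure": e})
    return CountTable(pd.DataFrame(rows), scheme=scheme, regions=("N",))


def intercept_design(table):
    return encode_design(ModelSpec(main_terms=()), table)


class TestLogJoint:
    def test_matches_scipy_composition(self):
        # oracle: assemble the same density from scipy.stats building blocks
        rng = np.random.default_rng(0)
        table = tiny_table([0, 2, 7, 31], [1.0, 1.0, 5.0, 40.0])
        design = intercept_design(table)
        beta = np.array([0.3])
        sigma2 = 0.5
        eta = rng.normal(size=4)
        expected = (
            stats.poisson.logpmf(table.counts, np.exp(eta) * table.exposures).sum()
            + stats.norm.logpdf(eta, design.X @ beta, np.sqrt(sigma2)).sum()
            + stats.norm.logpdf(beta, 0.0, np.sqrt(BETA_PRIOR_VAR)).sum()
            + stats.invgamma.logpdf(sigma2, 1.0, scale=0.001)
        )
        assert log_joint(beta, sigma2, eta, design, table) == pytest.approx(expected)

    def test_poisson_term_values(self):
        # C=0, E=1, eta=0 contributes -1; C=2 contributes -1 - log 2
        t0 = tiny_table([0], [1.0])
        t2 = tiny_table([2], [1.0])
        d = intercept_design(t0)
        args = (np.array([0.0]), 1.0, np.zeros(1))
        diff = log_joint(*args, d, t2) - log_joint(*args, d, t0)
        assert diff == pytest.approx(-np.log(2.0))
        assert poisson_loglik(np.array([0.0]), np.array([1.0])) == pytest.approx(-1.0)
        assert poisson_loglik(np.array([2.0]), np.array([1.0])) == pytest.approx(
            -1.0 - np.log(2.0))

    def test_location_invariance_of_latent_stage(self):
        # shifting eta and the intercept together changes only the Poisson
        # and beta-prior terms
        table = tiny_table([3, 4, 5], [2.0, 2.0, 2.0])
        design = intercept_design(table)
        beta = np.array([0.2])
        sigma2 = 0.3
        eta = np.array([0.1, -0.4, 0.6])
        c = 0.7
        j0 = log_joint(beta, sigma2, eta, design, table)
        j1 = log_joint(beta + c, sigma2, eta + c, design, table)
        poisson_change = (table.counts * c
                          - table.exposures * (np.exp(eta + c) - np.exp(eta))).sum()
        prior_change = (stats.norm.logpdf(beta + c, 0, np.sqrt(BETA_PRIOR_VAR))
                        - stats.norm.logpdf(beta, 0, np.sqrt(BETA_PRIOR_VAR))).sum()
        assert j1 - j0 == pytest.approx(poisson_change + prior_change)

    def test_nonpositive_sigma2_rejected(self):
        table = tiny_table([1], [1.0])
        design = intercept_design(table)
        assert log_joint(np.zeros(1), 0.0, np.zeros(1), design, table) == -np.inf


class TestMarginalMoments:
    def test_poisson_limit(self):
        m, v = marginal_moments(0.0, 0.0, 100.0)
        assert (m, v) == (100.0, 100.0)

    def test_against_monte_carlo(self):
        # oracle: sample theta ~ Lognormal then C ~ Poisson
        rng = np.random.default_rng(123)
        linpred, sigma2, E = 0.0, 0.1, 100.0
        n = 200_000
        theta = rng.lognormal(mean=linpred, sigma=np.sqrt(sigma2), size=n)
        counts = rng.poisson(theta * E)
        m, v = marginal_moments(linpred, sigma2, E)
        assert m == pytest.approx(E * np.exp(sigma2 / 2))
        assert abs(counts.mean() - m) < 3 * counts.std() / np.sqrt(n)
        mu4 = np.mean((counts - counts.mean()) ** 4)
        se_var = np.sqrt((mu4 - v ** 2) / n)
        assert abs(counts.var(ddof=1) - v) < 3 * se_var

    def test_dispersion_increases_with_sigma2(self):
        sig = np.linspace(0.0, 1.0, 11)
        ratios = [marginal_moments(0.0, s, 50.0)[1] / marginal_moments(0.0, s, 50.0)[0]
                  for s in sig]
        assert np.all(np.diff(ratios) > 0)


class TestMarginalLoglik:
    def test_sigma2_zero_equals_poisson(self):
        table = tiny_table([0, 3, 10, 120], [1.0, 2.0, 9.0, 100.0])
        design = intercept_design(table)
        beta = np.array([0.4])
        ll = marginal_loglik(beta, 0.0, design, table)
        expected = poisson_loglik(table.counts, np.exp(design.X @ beta) * table.exposures)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_against_monte_carlo_integration(self):
        # brute-force MC oracle for the latent integral on a 5-cell instance
        rng = np.random.default_rng(7)
        table = tiny_table([0, 2, 5, 40, 400], [1.0, 1.0, 4.0, 50.0, 380.0])
        design = intercept_design(table)
        beta, sigma2 = np.array([0.1]), 0.3
        mu = design.X @ beta
        n_mc = 200_000
        total_se = 0.0
        expected = 0.0
        for i in range(len(table)):
            eta = rng.normal(mu[i], np.sqrt(sigma2), size=n_mc)
            pmf = stats.poisson.pmf(table.counts[i], np.exp(eta) * table.exposures[i])
            expected += np.log(pmf.mean())
            total_se += (pmf.std() / (pmf.mean() * np.sqrt(n_mc))) ** 2
        ll = marginal_loglik(beta, sigma2, design, table, n_nodes=60)
        assert abs(ll - expected) < 3 * np.sqrt(total_se)

    def test_quadrature_refinement_converges(self):
        table = tiny_table([0, 2, 5, 40, 400], [1.0, 1.0, 4.0, 50.0, 380.0])
        design = intercept_design(table)
        beta, sigma2 = np.array([0.1]), 0.3
        l40 = marginal_loglik(beta, sigma2, design, table, n_nodes=40)
        l80 = marginal_loglik(beta, sigma2, design, table, n_nodes=80)
        assert abs(l40 - l80) < 1e-6


class TestGibbsSteps:
    def test_beta_full_conditional_matches_closed_form(self):
        # empirical moments of the sampler step vs the conjugate posterior
        rng = np.random.default_rng(11)
        n, p = 60, 3
        X = rng.normal(size=(n, p))
        eta = rng.normal(size=n)
        sigma2 = 0.7
        mean, cov = beta_conditional(X, eta, sigma2)
        # independent derivation: GLS on the augmented (ridge) system
        A = X.T @ X / sigma2 + np.eye(p) / BETA_PRIOR_VAR
        assert np.allclose(mean, np.linalg.solve(A, X.T @ eta / sigma2))
        draws = np.array([draw_beta(rng, X.T @ X, X.T @ eta, sigma2)
                          for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), mean, atol=4 * np.sqrt(np.diag(cov) / 4000))
        assert np.allclose(np.cov(draws.T), cov, atol=0.15 * np.abs(cov).max())

    def test_sigma2_step_with_no_data_samples_prior(self):
        # detailed-balance smoke test: the full conditional with an empty
        # residual vector must reproduce the Inverse-Gamma(1, 0.001) prior
        rng = np.random.default_rng(21)
        draws = np.array([draw_sigma2(rng, np.empty(0)) for _ in range(20000)])
        qs = [0.1, 0.25, 0.5, 0.75, 0.9]
        expected = stats.invgamma.ppf(qs, 1.0, scale=0.001)
        observed = np.quantile(draws, qs)
        assert np.allclose(observed, expected, rtol=0.1)


@pytest.fixture(scope="module")
def desk_fit():
    cfg = default_scenario(seed=17)
    truth = generate_scenario(cfg)
    table = simulate_counts(truth)
    mc = MCMCConfig(iterations=4000, burn_in=1000, thinning=2)
    fit = fit_mcmc(truth.design, table, mc, seed=100)
    return truth, table, fit, mc


class TestFitMCMC:
    def test_seed_reproducibility(self, desk_fit):
        truth, table, fit, mc = desk_fit
        fit2 = fit_mcmc(truth.design, table, mc, seed=100)
        assert np.array_equal(fit.beta, fit2.beta)
        assert np.array_equal(fit.sigma2, fit2.sigma2)
        assert np.array_equal(fit.eta, fit2.eta)

    def test_recovers_truth_on_one_replicate(self, desk_fit):
        truth, _, fit, _ = desk_fit
        ci = fit.beta_interval()
        inside = (truth.beta_true >= ci[:, 0]) & (truth.beta_true <= ci[:, 1])
        assert inside.mean() >= 0.85
        # the posterior concentrates on the realised latent variance of this
        # replicate, not the population sigma2, so compare against that
        realised = (np.log(truth.latent_rates)
                    - truth.design.X @ truth.beta_true).var(ddof=1)
        lo, hi = np.quantile(fit.sigma2, [0.025, 0.975])
        assert lo < realised < hi

    def test_two_seeds_agree_gelman_rubin(self, desk_fit):
        truth, table, fit, mc = desk_fit
        fit2 = fit_mcmc(truth.design, table, mc, seed=200)
        # split-free two-chain potential scale reduction per coefficient
        chains = np.stack([fit.beta, fit2.beta])  # 2 x draws x p
        m, d, _ = chains.shape
        within = chains.var(axis=1, ddof=1).mean(axis=0)
        between = d * chains.mean(axis=1).var(axis=0, ddof=1)
        rhat = np.sqrt(((d - 1) / d * within + between / d) / within)
        assert np.all(rhat < 1.1)

    def test_agrees_with_ml_poisson_oracle_when_no_overdispersion(self):
        # sigma2 = 0, large counts: posterior means must match a plain
        # Poisson GLM fitted by statsmodels
        import statsmodels.api as sm

        cfg = default_scenario(seed=23, true_sigma2=0.0, exposure_scale=5e5)
        truth = generate_scenario(cfg)
        table = simulate_counts(truth)
        fit = fit_mcmc(truth.design, table,
                       MCMCConfig(iterations=4000, burn_in=1000, thinning=2), seed=3)
        glm = sm.GLM(table.counts, truth.design.X,
                     family=sm.families.Poisson(),
                     offset=np.log(table.exposures)).fit()
        sd = fit.beta.std(axis=0)
        assert np.all(np.abs(fit.beta_mean - glm.params) < 2.5 * sd)
        assert fit.sigma2_mean < 0.01

    def test_degenerate_draws_are_plugin_linpred(self, desk_fit):
        truth, _, _, _ = desk_fit
        deg = PosteriorDraws.degenerate(truth.beta_true, 0.05, truth.design)
        assert np.allclose(deg.eta[0], truth.design.X @ truth.beta_true)

    def test_fitted_rates_positive_ordered_intervals(self, desk_fit):
        _, _, fit, _ = desk_fit
        summ = fit.fitted_rates().summary()
        assert (summ["lo95"] <= summ["hi95"]).all()
        assert (summ["mean"] > 0).all()
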