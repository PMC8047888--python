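import numpy as np
import pytest
from scipy import linalg, stats

import removalopt as ro
from conftest import make_posterior


def _toy_draw(path3, T=2):
    rng = np.random.default_rng(5)
    return ro.ParameterDraw(
        alpha=1.2, lam=-0.3, beta=np.array([0.1, -0.2, 0.05, 0.0, 0.3]),
        beta6=-0.25, gamma=0.6, sigma_rho=0.8, sigma_omega=0.4,
        sigma_e=0.5, sigma_1=1.1,
        rho=rng.normal(0, 0.5, 3), omega=rng.normal(0, 0.3, T - 1),
        mu=rng.normal(-1, 0.5, (3, T)),
    )


def _toy_dataset(path3, T=2):
    E = np.array([[10.0, 20.0], [np.nan, 15.0], [5.0, 0.0]])[:, :T]
    C = np.array([[1.0, 3.0], [np.nan, 2.0], [0.0, 0.0]])[:, :T]
    return ro.RemovalDataset(path3, tuple(range(1, T + 1)), E, C)


class TestLogJointDensity:
    def test_matches_term_by_term_oracle(self, path3):
        """Hand-summed density: every factor evaluated independently with
        scipy.stats on a 3-unit, 2-year toy."""
        draw = _toy_draw(path3)
        ds = _toy_dataset(path3)
        got = ro.log_joint_density(draw, ds)

        expected = 0.0
        # observation: only non-missing cells
        for i in range(3):
            for t in range(2):
                if not np.isnan(ds.effort[i, t]):
                    lam = ds.effort[i, t] * np.exp(draw.mu[i, t])
                    expected += stats.poisson.logpmf(int(ds.captures[i, t]), lam)
        # process: one transition; missing effort enters as zero trap-days
        h = path3.covariates @ draw.beta
        for i in range(3):
            e = 0.0 if np.isnan(ds.effort[i, 0]) else ds.effort[i, 0] / 100.0
            m = (draw.alpha + draw.lam * draw.mu[i, 0] + h[i]
                 + draw.beta6 * e + draw.rho[i] + draw.omega[0])
            expected += stats.norm.logpdf(draw.mu[i, 1], m, draw.sigma_e)
        # year effect, initial state
        expected += stats.norm.logpdf(draw.omega[0], 0, draw.sigma_omega)
        expected += stats.norm.logpdf(draw.mu[:, 0], 0, draw.sigma_1).sum()
        # CAR joint via multivariate normal
        P = (np.diag(path3.neighbor_counts) - draw.gamma * path3.adjacency_matrix)
        cov = linalg.inv(P) * draw.sigma_rho**2
        expected += stats.multivariate_normal.logpdf(draw.rho, mean=np.zeros(3), cov=cov)
        # priors
        expected += stats.halfnorm.logpdf(draw.sigma_omega, scale=10).sum()
        expected += stats.halfnorm.logpdf(draw.sigma_1, scale=10).sum()

        assert got == pytest.approx(expected, rel=1e-10)

    def test_single_cell_observation_term(self, path3):
        """E=10, C=1, mu=log(0.1): the observation factor is Poisson(1; 1),
        log-probability exactly -1 (isolated as a difference of joints on a
        single-year dataset, where no process term can shift)."""
        ds1 = _toy_dataset(path3, T=1)
        draw = _toy_draw(path3, T=1)
        draw.mu[0, 0] = np.log(0.1)
        base = ro.log_joint_density(draw, ds1)
        # same dataset but with cell (0, 0) missing
        E = ds1.effort.copy(); C = ds1.captures.copy()
        E[0, 0] = np.nan; C[0, 0] = np.nan
        ds0 = ro.RemovalDataset(path3, ds1.years, E, C)
        assert base - ro.log_joint_density(draw, ds0) == pytest.approx(-1.0)

    def test_gamma_outside_support_rejected(self, path3):
        draw = _toy_draw(path3)
        ds = _toy_dataset(path3)
        draw.gamma = 1.4
        assert ro.log_joint_density(draw, ds) == -np.inf

    def test_dimension_mismatch_rejected(self, path3):
        draw = _toy_draw(path3)
        draw.rho = draw.rho[:2]
        with pytest.raises(ValueError):
            ro.log_joint_density(draw, _toy_dataset(path3))


class TestComputeRhat:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 1000))
        assert 1.0 <= ro.compute_rhat(chains) <= 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert ro.compute_rhat(chains) > 3.0

    def test_degenerate_constant_chains(self):
        assert ro.compute_rhat([[1.0, 1.0], [1.0, 1.0]]) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            ro.compute_rhat([[1.0, 2.0, 3.0]])

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 400)) + rng.normal(0, 0.2, (4, 1))
        ours = ro.compute_rhat(chains)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0], method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestPosteriorPredictiveCheck:
    def test_extreme_discrepancy_gives_zero(self, path3):
        samples = make_posterior(path3, n_draws=50, n_years=2, alpha=np.log(0.01))
        samples.mu[:] = np.log(0.01)
        E = np.full((3, 2), 100.0)
        C = np.full((3, 2), 500.0)  # far above every replicate
        ds = ro.RemovalDataset(path3, (1, 2), E, C)
        pv = ro.posterior_predictive_check(samples, ds, seed=0)
        assert all(p == 0.0 for p in pv.values())

    def test_values_are_probabilities(self, small_fit, small_sim):
        pv = ro.posterior_predictive_check(small_fit, small_sim.dataset, seed=1)
        assert all(0.0 <= p <= 1.0 for p in pv.values())


class TestFixedEffectContribution:
    def test_zero_betas_give_delta_zero(self, path3):
        s = make_posterior(path3, n_draws=3, rho=np.array([0.3, -0.2, 0.6]))
        out = ro.fixed_effect_contribution(s, path3)
        assert out.median == 0.0 and out.n_excluded == 0

    def test_constant_rho_gives_delta_one(self, path3):
        s = make_posterior(path3, n_draws=3, beta=np.ones(5),
                           rho=np.full(3, 0.7))
        out = ro.fixed_effect_contribution(s, path3)
        assert out.median == 1.0

    def test_degenerate_draws_excluded(self, path3):
        s = make_posterior(path3, n_draws=4)
        s.beta[:2] = 0.3  # two informative draws, two with V1 + V2 = 0
        out = ro.fixed_effect_contribution(s, path3)
        assert out.n_excluded == 2 and len(out.delta_draws) == 2


class TestFitMCMC:
    def test_draw_count_follows_config(self, small_fit):
        assert small_fit.n_draws == 4 * 250
        assert small_fit.n_draws == small_fit.n_kept

    def test_default_config_keeps_5000(self):
        assert ro.MCMCConfig().n_chains * ro.MCMCConfig().kept_per_chain == 5000

    def test_rhat_recorded_for_all_scalars(self, small_fit):
        expected = {"alpha", "lambda", "beta1", "beta2", "beta3", "beta4",
                    "beta5", "beta6", "gamma", "sigma_rho", "sigma_omega",
                    "sigma_e", "sigma_1"}
        assert set(small_fit.rhat) == expected
        assert all(r >= 0.97 for r in small_fit.rhat.values())

    def test_recovers_effort_effect(self, small_fit, small_sim):
        tr = small_fit.scalar_trace("beta6")
        truth = small_sim.params.beta6
        assert abs(tr.mean() - truth) < 4 * tr.std()

    def test_chains_mixed(self, small_fit):
        assert max(small_fit.rhat.values()) < 1.2

    def test_reproducible_given_seed(self, small_sim):
        cfg = ro.MCMCConfig(n_chains=2, iterations=60, warmup=30, thin=2, seed=5)
        a = ro.fit_mcmc(small_sim.dataset, cfg)
        b = ro.fit_mcmc(small_sim.dataset, cfg)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.alpha, b.alpha)
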