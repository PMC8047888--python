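import numpy as np
import pytest

import removalopt as ro


@pytest.fixture(scope="session")
def path3():
    """3-unit path network u1 - u2 - u3 with fixed covariates."""
    cov = ro.network.standardize_columns(
        np.random.default_rng(0).standard_normal((3, 5))
    )
    return ro.RiverNetwork(unit_ids=("u1", "u2", "u3"), covariates=cov,
                           edges=((0, 1), (1, 2)))


def make_posterior(network, n_draws=1, n_years=9, *, alpha=1.9, lam=-0.16,
                   beta=None, beta6=-0.26, gamma=0.5, sigma_rho=0.5,
                   sigma_omega=0.2, sigma_e=0.3, sigma_1=1.0, rho=None,
                   mu_final=None, jitter=0.0, seed=0):
    """Hand-built PosteriorSamples (constant or jittered draws) for tests
    that need a posterior without running MCMC."""
    rng = np.random.default_rng(seed)
    I = network.n_units
    N = n_draws
    beta = np.zeros(5) if beta is None else np.asarray(beta, float)
    rho = np.zeros(I) if rho is None else np.asarray(rho, float)

    def rep(x, shape):
        base = np.broadcast_to(np.asarray(x, float), shape).copy()
        if jitter:
            base += jitter * rng.standard_normal(shape)
        return base

    mu = np.zeros((N, I, n_years))
    if mu_final is not None:
        mu[:, :, -1] = np.broadcast_to(mu_final, (N, I))
    return ro.PosteriorSamples(
        alpha=rep(alpha, (N,)), lam=rep(lam, (N,)),
        beta=rep(beta, (N, 5)), beta6=rep(beta6, (N,)),
        gamma=np.full(N, gamma), sigma_rho=np.full(N, sigma_rho),
        sigma_omega=rep(sigma_omega, (N,)), sigma_e=rep(sigma_e, (N,)),
        sigma_1=np.full(N, sigma_1),
        rho=rep(rho, (N, I)), omega=np.zeros((N, n_years - 1)), mu=mu,
        n_chains=1, n_kept=N, thin=1,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Reduced synthetic study (15 units, 7 years) with known truth."""
    cfg = ro.ScenarioConfig(n_units=15, n_years=7)
    return ro.generate_dataset(cfg, seed=314)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """One MCMC fit of the reduced study, shared across tests."""
    cfg = ro.MCMCConfig(n_chains=4, iterations=1500, warmup=750, thin=3, seed=2718)
    return ro.fit_mcmc(small_sim.dataset, cfg)
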