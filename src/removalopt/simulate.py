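"""Synthetic removal datasets with the exact statistical structure the
state-space model assumes.

Process model (log relative density mu, annual steps):

    mu[i, 1]   ~ Normal(0, sigma_1^2)
    mu[i, t+1] = alpha + lambda * mu[i, t] + sum_k beta_k H[k, i]
                 + beta6 * E[i, t] / 100 + rho_i + omega_t + e[i, t]

with omega_t ~ N(0, sigma_omega^2) shared across units within a year,
e[i, t] ~ N(0, sigma_e^2) unit-year noise and rho a proper CAR field.

Observation model:  C[i, t] ~ Poisson(E[i, t] * exp(mu[i, t])), so exp(mu)
is the expected catch per trap-day (CPUE), the relative-density index.
Effort is stored in raw trap-days throughout; the process model divides by
100 at its single usage site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .car import sample_car_field
from .network import RiverNetwork, generate_river_network

EFFORT_SCALE = 100.0  # beta6 is the effect per 100 trap-days


@dataclass
class TrueParameters:
    """Generating parameters of the Gompertz state-space model."""

    alpha: float = 1.9
    lam: float = -0.16
    beta: np.ndarray = field(default_factory=lambda: np.array([-0.05, -0.04, 0.18, 0.11, 0.01]))
    beta6: float = -0.26
    gamma: float = 0.5
    sigma_rho: float = 0.5
    sigma_omega: float = 0.2
    sigma_e: float = 0.3
    sigma_1: float = 1.0
    rho: Optional[np.ndarray] = None
    omega: Optional[np.ndarray] = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        for name in ("sigma_rho", "sigma_omega", "sigma_e", "sigma_1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.rho is not None:
            self.rho = np.asarray(self.rho, dtype=float)
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float)


@dataclass
class RemovalDataset:
    """Removal records on a river network.

    ``effort`` and ``captures`` are (I, T) arrays in trap-days and
    individuals; NaN marks unit-years with no trapping record (missing).
    A recorded zero effort is a valid observation that forces zero
    captures.
    """

    network: RiverNetwork
    years: tuple
    effort: np.ndarray
    captures: np.ndarray

    def __post_init__(self):
        self.years = tuple(self.years)
        E = np.asarray(self.effort, dtype=float)
        C = np.asarray(self.captures, dtype=float)
        I, T = self.network.n_units, len(self.years)
        if E.shape != (I, T) or C.shape != (I, T):
            raise ValueError(
                f"effort/captures must be ({I}, {T}); got {E.shape}, {C.shape}"
            )
        if not np.array_equal(np.isnan(E), np.isnan(C)):
            raise ValueError("captures must be missing exactly where effort is missing")
        obs = ~np.isnan(E)
        if np.any(E[obs] < 0):
            raise ValueError("effort must be nonnegative")
        c = C[obs]
        if np.any(c < 0) or np.any(c != np.round(c)):
            raise ValueError("captures must be nonnegative integers")
        if np.any(c[E[obs] == 0] > 0):
            raise ValueError("captures recorded with zero effort")
        self.effort = E
        self.captures = C

    @property
    def n_units(self) -> int:
        return self.network.n_units

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of unit-years with a trapping record."""
        return ~np.isnan(self.effort)

    @property
    def total_cpue(self) -> float:
        """Whole-dataset captures per trap-day over observed unit-years."""
        obs = self.observed
        return float(np.nansum(self.captures[obs]) / np.nansum(self.effort[obs]))


def simulate_population(
    network: RiverNetwork,
    params: TrueParameters,
    effort: np.ndarray,
    seed=None,
    years: Optional[tuple] = None,
):
    """Simulate latent log-densities and Poisson captures under an effort
    schedule.

    ``effort`` is (I, T) in trap-days with NaN for unit-years without
    trapping; the process model treats those years as zero removal effort
    while the observation is simply absent.  If ``params.rho`` /
    ``params.omega`` are None, they are drawn fresh (CAR field, iid normal
    year effects) from dedicated substreams of the seed.

    Returns ``(mu, dataset)`` with mu the (I, T) latent matrix.
    """
    E = np.asarray(effort, dtype=float)
    if E.ndim != 2 or E.shape[0] != network.n_units:
        raise ValueError(f"effort must be (I, T); got {E.shape}")
    obs = ~np.isnan(E)
    if np.any(E[obs] < 0):
        raise ValueError("effort must be nonnegative")
    I, T = E.shape
    yrs = tuple(years) if years is not None else tuple(range(1, T + 1))

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_field, rng_proc, rng_obs = (np.random.default_rng(s) for s in ss.spawn(3))

    rho = params.rho
    if rho is None:
        rho = (
            sample_car_field(network, params.gamma, params.sigma_rho, seed=rng_field)
            if params.sigma_rho > 0
            else np.zeros(I)
        )
    omega = params.omega
    if omega is None:
        omega = rng_proc.normal(0.0, params.sigma_omega, size=T - 1) if params.sigma_omega > 0 else np.zeros(T - 1)
    if len(rho) != I or len(omega) != T - 1:
        raise ValueError("rho must have length I and omega length T-1")

    h = network.covariates @ params.beta
    ee = np.where(obs, E, 0.0) / EFFORT_SCALE

    mu = np.empty((I, T))
    mu[:, 0] = rng_proc.normal(0.0, params.sigma_1, size=I) if params.sigma_1 > 0 else 0.0
    for t in range(T - 1):
        e_noise = rng_proc.normal(0.0, params.sigma_e, size=I) if params.sigma_e > 0 else 0.0
        mu[:, t + 1] = (
            params.alpha
            + params.lam * mu[:, t]
            + h
            + params.beta6 * ee[:, t]
            + rho
            + omega[t]
            + e_noise
        )

    C = np.full((I, T), np.nan)
    mean = np.where(obs, E, 0.0) * np.exp(mu)
    C[obs] = rng_obs.poisson(mean[obs]).astype(float)

    realized = replace(params, rho=rho, omega=omega)
    return mu, RemovalDataset(network=network, years=yrs, effort=E, captures=C), realized


@dataclass
class ScenarioConfig:
    """Description of a complete synthetic study.

    Defaults emulate the motivating removal program: 75 river sections
    observed over 9 annual trapping seasons, effort of order a couple of
    thousand trap-days per trapped unit-year (lognormal across unit-years),
    and roughly one unit-year in ten without any traps.
    """

    n_units: int = 75
    n_years: int = 9
    branching: float = 0.15
    params: TrueParameters = field(default_factory=TrueParameters)
    effort_log_mean: float = float(np.log(2000.0))
    effort_log_sd: float = 0.15
    missing_prob: float = 0.1

    def __post_init__(self):
        if self.n_units < 2 or self.n_years < 2:
            raise ValueError("need n_units >= 2 and n_years >= 2")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.params.rho is not None and len(self.params.rho) != self.n_units:
            raise ValueError("params.rho length inconsistent with n_units")
        if self.params.omega is not None and len(self.params.omega) != self.n_years - 1:
            raise ValueError("params.omega length inconsistent with n_years")


@dataclass
class SimulationResult:
    dataset: RemovalDataset
    params: TrueParameters
    mu: np.ndarray


def generate_dataset(config: Optional[ScenarioConfig] = None, seed=None) -> SimulationResult:
    """Generate a full synthetic study: network, effort schedule, latent
    states, captures and the generating parameters (for recovery tests)."""
    cfg = config if config is not None else ScenarioConfig()
    ss = np.random.SeedSequence(seed)
    s_net, s_effort, s_pop = ss.spawn(3)
    network = generate_river_network(cfg.n_units, cfg.branching, seed=s_net)
    rng = np.random.default_rng(s_effort)
    E = rng.lognormal(cfg.effort_log_mean, cfg.effort_log_sd, size=(cfg.n_units, cfg.n_years))
    E = np.round(E)
    if cfg.missing_prob > 0:
        E[rng.random(E.shape) < cfg.missing_prob] = np.nan
        # keep at least one observed year per unit so every unit informs the fit
        for i in np.where(np.all(np.isnan(E), axis=1))[0]:
            E[i, int(rng.integers(cfg.n_years))] = np.round(
                rng.lognormal(cfg.effort_log_mean, cfg.effort_log_sd)
            )
    mu, dataset, realized = simulate_population(network, cfg.params, E, seed=s_pop)
    return SimulationResult(dataset=dataset, params=realized, mu=mu)
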