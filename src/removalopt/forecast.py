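"""Forward simulation of the managed population under a fixed allocation.

Starting from each posterior draw's final-year latent state, the process
model is iterated with fresh stochastic year effects (shared across units
within a year) and unit-year noise, under the candidate effort allocation.
The resulting ensemble of relative-density trajectories answers "how many
years until the whole-area mean CPUE falls below the management target?".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibrium import Allocation
from .model import PosteriorSamples
from .network import RiverNetwork
from .simulate import EFFORT_SCALE


@dataclass
class TrajectoryEnsemble:
    """densities[n, i, t] = relative density exp(mu) of unit i in
    simulation year t+1 (t = 0 .. horizon-1) under posterior draw n."""

    densities: np.ndarray
    allocation: Allocation
    horizon: int

    def __post_init__(self):
        if self.densities.ndim != 3 or self.densities.shape[2] != self.horizon:
            raise ValueError("densities must be (n_draws, I, horizon)")
        if np.any(self.densities <= 0):
            raise ValueError("relative densities must be positive")

    @property
    def area_mean(self) -> np.ndarray:
        """(n_draws, horizon) whole-area mean relative density per year."""
        return self.densities.mean(axis=1)

    def summary(self, target: float = 0.03) -> pd.DataFrame:
        am = self.area_mean
        q05, q50, q95 = np.quantile(am, [0.05, 0.5, 0.95], axis=0)
        return pd.DataFrame({
            "year": np.arange(1, self.horizon + 1),
            "mean_density": am.mean(axis=0),
            "q05": q05, "q50": q50, "q95": q95,
            "frac_below_target": (am < target).mean(axis=0),
        })


def forward_simulate(samples: PosteriorSamples, network: RiverNetwork,
                     allocation: Allocation, horizon: int = 20,
                     seed=None) -> TrajectoryEnsemble:
    """Simulate `horizon` years forward per posterior draw.

    Each draw starts from its own final-year latent state mu[:, T]; each
    simulated year applies the Gompertz recursion with that draw's
    parameters, fresh omega ~ N(0, sigma_omega^2) shared across units, and
    fresh e ~ N(0, sigma_e^2) per unit.  Reproducible given seed.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if len(allocation.effort) != network.n_units:
        raise ValueError("allocation length does not match network")
    rng = np.random.default_rng(seed)
    N, I = samples.n_draws, network.n_units
    h = samples.beta @ network.covariates.T  # (N, I)
    ee = allocation.effort / EFFORT_SCALE
    fixed = (
        samples.alpha[:, None] + h + samples.beta6[:, None] * ee[None, :]
        + samples.rho
    )
    mu = samples.mu[:, :, -1].copy()
    dens = np.empty((N, I, horizon))
    for t in range(horizon):
        omega = rng.standard_normal(N) * samples.sigma_omega
        e = rng.standard_normal((N, I)) * samples.sigma_e[:, None]
        mu = fixed + samples.lam[:, None] * mu + omega[:, None] + e
        dens[:, :, t] = np.exp(mu)
    return TrajectoryEnsemble(densities=dens, allocation=allocation, horizon=horizon)


def time_to_threshold(ensemble: TrajectoryEnsemble, threshold: float = 0.03):
    """First simulation year whose whole-area mean relative density is
    below the threshold, per draw.

    Returns ``(years, median_year, frac_reached)``: ``years`` has NaN for
    draws that never cross within the horizon; the ensemble median is
    ``inf`` when fewer than half the draws reach the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    below = ensemble.area_mean < threshold  # (n_draws, horizon)
    reached = below.any(axis=1)
    first = np.argmax(below, axis=1) + 1.0
    years = np.where(reached, first, np.nan)
    frac = float(reached.mean())
    median = float(np.median(years[reached])) if frac >= 0.5 else math.inf
    return years, median, frac
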