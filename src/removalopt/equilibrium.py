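"""Equilibrium densities and the management objective U(E).

For |lambda| < 1 the noise-free Gompertz recursion converges, per unit, to

    mu*_i = (alpha + sum_k beta_k H_ki + beta6 E_i / 100 + rho_i) / (1 - lambda)

The objective is the posterior mean over retained MCMC draws of the summed
equilibrium density K(E) = sum_i 100 * exp(mu*_i).  The factor 100 puts K
and U on a per-100-trap-day reporting scale, so the whole-area mean
relative density (expected CPUE per trap-day) is U / (100 I).  Draws with
|lambda| >= 1 have no equilibrium and are excluded with a reported count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import ParameterDraw, PosteriorSamples
from .network import RiverNetwork
from .simulate import EFFORT_SCALE

REPORT_SCALE = 100.0  # printed objective = sum_i 100 exp(mu*_i)


@dataclass
class Allocation:
    """Nonnegative per-unit efforts (trap-days) summing to a fixed total."""

    effort: np.ndarray
    total: float

    def __post_init__(self):
        e = np.asarray(self.effort, dtype=float)
        if np.any(e < 0) or not np.all(np.isfinite(e)):
            raise ValueError("allocation efforts must be finite and >= 0")
        if abs(e.sum() - self.total) > 1e-6 * max(self.total, 1.0):
            raise ValueError(
                f"allocation sums to {e.sum()}, expected total {self.total}"
            )
        self.effort = e
        self.total = float(self.total)

    @classmethod
    def uniform(cls, n_units: int, total: float) -> "Allocation":
        return cls(effort=np.full(n_units, total / n_units), total=total)

    @classmethod
    def from_effort(cls, effort) -> "Allocation":
        e = np.asarray(effort, dtype=float)
        return cls(effort=e, total=float(e.sum()))

    def scaled(self, multiplier: float) -> "Allocation":
        return Allocation(effort=self.effort * multiplier, total=self.total * multiplier)


@dataclass
class ObjectiveResult:
    """Posterior-mean summed equilibrium density and derived summaries."""

    U: float
    mean_relative_density: float
    invalid_draw_count: int
    per_draw_K: Optional[np.ndarray] = None


def equilibrium_log_density(draw: ParameterDraw, network: RiverNetwork,
                            allocation: Allocation) -> np.ndarray:
    """Per-unit equilibrium log relative density mu*_i for one draw.

    Raises ValueError when |lambda| >= 1 (no equilibrium exists); callers
    averaging over draws must exclude and count such draws instead of
    silently including them.
    """
    if abs(draw.lam) >= 1.0:
        raise ValueError(f"no equilibrium: |lambda| = {abs(draw.lam)} >= 1")
    if len(allocation.effort) != network.n_units:
        raise ValueError("allocation length does not match network")
    lin = (
        draw.alpha + network.covariates @ draw.beta
        + draw.beta6 * allocation.effort / EFFORT_SCALE + draw.rho
    )
    return lin / (1.0 - draw.lam)


class EquilibriumObjective:
    """Fast evaluator of U(E) with per-draw coefficients precomputed.

    Writes mu*_{i,n} = (logc_{i,n} + b_n E_i) with
    logc_{i,n} = (alpha_n + H_i beta_n + rho_{i,n}) / (1 - lambda_n) and
    b_n = beta6_n / (100 (1 - lambda_n)), so one objective evaluation is a
    single (n_draws, I) exp-sum.
    """

    def __init__(self, logc: np.ndarray, b: np.ndarray, invalid_draw_count: int = 0):
        self.logc = np.asarray(logc, dtype=float)  # (n_draws, I)
        self.b = np.asarray(b, dtype=float)        # (n_draws,)
        if self.logc.ndim != 2 or self.b.shape != (self.logc.shape[0],):
            raise ValueError("logc must be (n_draws, I) and b (n_draws,)")
        if self.logc.shape[0] == 0:
            raise ValueError("no valid draws (all |lambda| >= 1)")
        self.invalid_draw_count = int(invalid_draw_count)

    @classmethod
    def from_samples(cls, samples: PosteriorSamples, network: RiverNetwork):
        valid = np.abs(samples.lam) < 1.0
        one_m_lam = 1.0 - samples.lam[valid]
        lin = (
            samples.alpha[valid, None]
            + samples.beta[valid] @ network.covariates.T
            + samples.rho[valid]
        )
        logc = np.log(REPORT_SCALE) + lin / one_m_lam[:, None]
        b = samples.beta6[valid] / (EFFORT_SCALE * one_m_lam)
        return cls(logc, b, invalid_draw_count=int(np.sum(~valid)))

    @classmethod
    def from_coefficients(cls, c: np.ndarray, b: np.ndarray):
        """Build directly from per-draw unit coefficients c_{n,i} (density
        at zero effort, already on the reporting scale) and per-draw
        effort coefficients b_n (per trap-day)."""
        c = np.atleast_2d(np.asarray(c, dtype=float))
        b = np.atleast_1d(np.asarray(b, dtype=float))
        return cls(np.log(c), b)

    @property
    def n_units(self) -> int:
        return self.logc.shape[1]

    @property
    def n_draws(self) -> int:
        return self.logc.shape[0]

    def per_draw_K(self, effort: np.ndarray) -> np.ndarray:
        return np.exp(self.logc + self.b[:, None] * effort[None, :]).sum(axis=1)

    def U(self, effort: np.ndarray) -> float:
        return float(self.per_draw_K(np.asarray(effort, dtype=float)).mean())

    def unit_density(self, effort: np.ndarray) -> np.ndarray:
        """Posterior-mean equilibrium density of each unit at the given
        per-unit efforts (reporting scale)."""
        return np.exp(self.logc + self.b[:, None] * effort[None, :]).mean(axis=0)

    def marginal(self, effort: np.ndarray) -> np.ndarray:
        """d/dE_i of the posterior-mean unit densities (all negative when
        beta6 < 0 in every draw)."""
        return (
            self.b[:, None]
            * np.exp(self.logc + self.b[:, None] * effort[None, :])
        ).mean(axis=0)


def objective_U(samples: PosteriorSamples, network: RiverNetwork,
                allocation: Allocation, keep_per_draw: bool = False) -> ObjectiveResult:
    """U(E): mean over valid posterior draws of K(E) on the printed scale."""
    ev = EquilibriumObjective.from_samples(samples, network)
    K = ev.per_draw_K(allocation.effort)
    U = float(K.mean())
    return ObjectiveResult(
        U=U,
        mean_relative_density=U / (REPORT_SCALE * network.n_units),
        invalid_draw_count=ev.invalid_draw_count,
        per_draw_K=K if keep_per_draw else None,
    )


def mean_cpue_vs_target(result: ObjectiveResult, target: float = 0.03):
    """Whether the whole-area mean relative density is strictly below the
    management target CPUE; returns (achieved, margin = target - density)."""
    if target <= 0:
        raise ValueError("target must be positive")
    margin = target - result.mean_relative_density
    return bool(result.mean_relative_density < target), float(margin)
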