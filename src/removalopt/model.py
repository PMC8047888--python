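"""Bayesian spatial Gompertz state-space model for removal records.

Hierarchy (I units, T years):

    observation   C[i,t] ~ Poisson(E[i,t] * exp(mu[i,t]))          (observed unit-years)
    process       mu[i,t+1] = alpha + lambda mu[i,t] + H_i . beta
                              + beta6 E[i,t]/100 + rho_i + omega_t + e[i,t]
    year effect   omega_t ~ N(0, sigma_omega^2)
    noise         e[i,t] ~ N(0, sigma_e^2)
    spatial       rho ~ properCAR(gamma, sigma_rho^2)  on the river graph
    initial       mu[i,1] ~ N(0, sigma_1^2)

Priors: flat on alpha, lambda, beta, beta6; flat-positive on sigma_e,
sigma_rho; half-normal(scale 10) on sigma_omega and sigma_1; Uniform(0,1)
on gamma (keeps the CAR precision positive definite).

Posterior sampling is Metropolis-within-Gibbs, exploiting the model's
conditional structure:

* (alpha, lambda, beta, beta6) — exact Gaussian block draw (conjugate
  linear regression given the latent states).
* rho — exact Gaussian draw (CAR prior precision + diagonal likelihood
  precision), one dense Cholesky solve per iteration.
* omega — independent Gaussian conditionals.
* mu — random-walk Metropolis on all cells, vectorized over units and
  over even/odd year slices (a valid two-colour update because a cell
  interacts only with its temporal neighbours), with per-cell step-size
  adaptation during warmup.
* sigma_e, sigma_omega, sigma_1, sigma_rho, gamma — univariate slice
  sampling on unbounded transforms.
* ancillary recentering moves that shift mass between alpha and the means
  of rho / omega (these are strongly confounded; the moves are symmetric
  Gaussian translation proposals accepted on the prior ratio).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, stats

from .network import RiverNetwork
from .simulate import EFFORT_SCALE, RemovalDataset

HALF_NORMAL_SCALE = 10.0  # prior scale of sigma_omega, sigma_1

_SCALAR_PARAMS = (
    "alpha", "lambda", "beta1", "beta2", "beta3", "beta4", "beta5",
    "beta6", "gamma", "sigma_rho", "sigma_omega", "sigma_e", "sigma_1",
)


@dataclass
class ParameterDraw:
    """One joint draw of all parameters and latent log-densities."""

    alpha: float
    lam: float
    beta: np.ndarray
    beta6: float
    gamma: float
    sigma_rho: float
    sigma_omega: float
    sigma_e: float
    sigma_1: float
    rho: np.ndarray
    omega: np.ndarray
    mu: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, stacked chain-major.

    ``mu`` has shape (n_draws, I, T); ``rho`` (n_draws, I); ``omega``
    (n_draws, T-1).  ``rhat`` maps scalar-parameter names to split-Rhat.
    """

    alpha: np.ndarray
    lam: np.ndarray
    beta: np.ndarray
    beta6: np.ndarray
    gamma: np.ndarray
    sigma_rho: np.ndarray
    sigma_omega: np.ndarray
    sigma_e: np.ndarray
    sigma_1: np.ndarray
    rho: np.ndarray
    omega: np.ndarray
    mu: np.ndarray
    n_chains: int = 1
    n_warmup: int = 0
    n_kept: int = 0
    thin: int = 1
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    seed: Optional[int] = None

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    def draw(self, n: int) -> ParameterDraw:
        return ParameterDraw(
            alpha=float(self.alpha[n]), lam=float(self.lam[n]),
            beta=self.beta[n], beta6=float(self.beta6[n]),
            gamma=float(self.gamma[n]), sigma_rho=float(self.sigma_rho[n]),
            sigma_omega=float(self.sigma_omega[n]), sigma_e=float(self.sigma_e[n]),
            sigma_1=float(self.sigma_1[n]), rho=self.rho[n],
            omega=self.omega[n], mu=self.mu[n],
        )

    def scalar_trace(self, name: str) -> np.ndarray:
        if name.startswith("beta") and name != "beta6":
            return self.beta[:, int(name[4:]) - 1]
        key = {"lambda": "lam"}.get(name, name)
        return getattr(self, key)


@dataclass
class MCMCConfig:
    """Sampler settings.  The default run keeps
    n_chains * (iterations - warmup) / thin = 5,000 draws."""

    n_chains: int = 4
    iterations: int = 10_000
    warmup: int = 5_000
    thin: int = 4
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.n_chains, self.iterations, self.thin) < 1 or self.warmup < 0:
            raise ValueError("chains, iterations, thin must be >= 1 and warmup >= 0")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.warmup + self.thin - 1) // self.thin


# ---------------------------------------------------------------------------
# log joint density (used by tests as the single source of truth)
# ---------------------------------------------------------------------------

def log_joint_density(draw: ParameterDraw, dataset: RemovalDataset) -> float:
    """Unnormalized log posterior density of one joint draw.

    Sums observation, process, CAR, year-effect, initial-state and prior
    terms; missing unit-years contribute no observation term.  Returns
    -inf outside the support (gamma outside (0,1), nonpositive SDs).
    """
    I, T = dataset.n_units, dataset.n_years
    if draw.mu.shape != (I, T) or len(draw.rho) != I or len(draw.omega) != T - 1:
        raise ValueError("draw dimensions do not match dataset")
    if not (0.0 < draw.gamma < 1.0):
        return -math.inf
    if min(draw.sigma_rho, draw.sigma_omega, draw.sigma_e, draw.sigma_1) <= 0:
        return -math.inf

    obs = dataset.observed
    E = np.where(obs, dataset.effort, 0.0)
    lp = float(
        np.sum(stats.poisson.logpmf(dataset.captures[obs], E[obs] * np.exp(draw.mu[obs])))
    )

    h = dataset.network.covariates @ draw.beta
    ee = E / EFFORT_SCALE
    pred = (
        draw.alpha + draw.lam * draw.mu[:, :-1] + h[:, None]
        + draw.beta6 * ee[:, :-1] + draw.rho[:, None] + draw.omega[None, :]
    )
    lp += float(np.sum(stats.norm.logpdf(draw.mu[:, 1:], pred, draw.sigma_e)))
    lp += float(np.sum(stats.norm.logpdf(draw.omega, 0.0, draw.sigma_omega)))
    lp += float(np.sum(stats.norm.logpdf(draw.mu[:, 0], 0.0, draw.sigma_1)))

    # proper CAR joint density of rho
    P = np.diag(dataset.network.neighbor_counts) - draw.gamma * dataset.network.adjacency_matrix
    sign, logdet = np.linalg.slogdet(P)
    if sign <= 0:
        return -math.inf
    q = float(draw.rho @ P @ draw.rho)
    lp += 0.5 * (logdet - I * math.log(draw.sigma_rho**2)) - q / (2 * draw.sigma_rho**2)
    lp -= 0.5 * I * math.log(2 * math.pi)

    # priors: half-normal(scale 10) on sigma_omega, sigma_1; flat elsewhere
    for s in (draw.sigma_omega, draw.sigma_1):
        lp += float(stats.halfnorm.logpdf(s, scale=HALF_NORMAL_SCALE))
    return lp


# ---------------------------------------------------------------------------
# slice sampler (Neal 2003, stepping out + shrinkage)
# ---------------------------------------------------------------------------

def _slice_sample(x0, logf, rng, w=1.0, lower=-np.inf, upper=np.inf, max_steps=50):
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise RuntimeError("slice sampler started outside support")
    logy = f0 + math.log(rng.uniform())
    u = rng.uniform()
    left = max(x0 - u * w, lower)
    right = min(left + w, upper)
    for _ in range(max_steps):
        if left <= lower or logf(left) < logy:
            break
        left = max(left - w, lower)
    for _ in range(max_steps):
        if right >= upper or logf(right) < logy:
            break
        right = min(right + w, upper)
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pragma: no cover - pathological shrinkage


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _ChainRunner:
    def __init__(self, dataset: RemovalDataset, cfg: MCMCConfig, rng: np.random.Generator):
        self.ds = dataset
        self.cfg = cfg
        self.rng = rng
        net = dataset.network
        self.I, self.T = dataset.n_units, dataset.n_years
        self.H = net.covariates
        self.W = net.adjacency_matrix
        self.k = net.neighbor_counts
        self.obs = dataset.observed
        self.E0 = np.where(self.obs, dataset.effort, 0.0)
        self.C0 = np.where(self.obs, dataset.captures, 0.0)
        self.ee = self.E0 / EFFORT_SCALE
        # eigenvalues of D^{-1/2} W D^{-1/2} for fast log det(D - gamma W)
        dmh = 1.0 / np.sqrt(self.k)
        self.car_eigs = np.linalg.eigvalsh(dmh[:, None] * self.W * dmh[None, :])
        self.logdet_D = float(np.sum(np.log(self.k)))
        self._init_state()

    def _init_state(self):
        rng = self.rng
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.log((self.C0 + 0.5) / np.maximum(self.E0, 1e-12))
        raw = np.where(self.obs & (self.E0 > 0), raw, np.nan)
        fill = np.nanmean(raw) if np.any(np.isfinite(raw)) else 0.0
        self.mu = np.where(np.isfinite(raw), raw, fill) + rng.normal(0, 0.3, (self.I, self.T))
        self.alpha = rng.normal(0, 1)
        self.lam = rng.uniform(-0.5, 0.5)
        self.beta = rng.normal(0, 0.1, self.H.shape[1])
        self.beta6 = rng.normal(0, 0.1)
        self.rho = rng.normal(0, 0.1, self.I)
        self.omega = rng.normal(0, 0.1, self.T - 1)
        self.sigma_e = rng.uniform(0.2, 0.8)
        self.sigma_rho = rng.uniform(0.2, 0.8)
        self.sigma_omega = rng.uniform(0.1, 0.5)
        self.sigma_1 = rng.uniform(0.5, 1.5)
        self.gamma = rng.uniform(0.2, 0.8)
        self.mu_step = np.full((self.I, self.T), 0.5)
        self.mu_acc = np.zeros((self.I, self.T))

    # ----- mu update ------------------------------------------------------
    def _mu_cond(self, vals: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Conditional log-density of the mu cells in ``cols`` at ``vals``
        (shape (I, len(cols))), other columns taken from current state."""
        h = self.H @ self.beta
        base = self.alpha + h[:, None] + self.rho[:, None]
        lp = np.where(
            self.obs[:, cols],
            self.C0[:, cols] * vals - self.E0[:, cols] * np.exp(vals),
            0.0,
        )
        for j, t in enumerate(cols):
            if t == 0:
                lp[:, j] -= vals[:, j] ** 2 / (2 * self.sigma_1**2)
            else:
                m_prev = (
                    base[:, 0] + self.lam * self.mu[:, t - 1]
                    + self.beta6 * self.ee[:, t - 1] + self.omega[t - 1]
                )
                lp[:, j] -= (vals[:, j] - m_prev) ** 2 / (2 * self.sigma_e**2)
            if t < self.T - 1:
                pred = (
                    base[:, 0] + self.lam * vals[:, j]
                    + self.beta6 * self.ee[:, t] + self.omega[t]
                )
                lp[:, j] -= (self.mu[:, t + 1] - pred) ** 2 / (2 * self.sigma_e**2)
        return lp

    def _update_mu(self):
        for parity in (0, 1):
            cols = np.arange(parity, self.T, 2)
            cur = self.mu[:, cols]
            prop = cur + self.mu_step[:, cols] * self.rng.standard_normal(cur.shape)
            dlp = self._mu_cond(prop, cols) - self._mu_cond(cur, cols)
            acc = np.log(self.rng.uniform(size=cur.shape)) < dlp
            new = np.where(acc, prop, cur)
            self.mu[:, cols] = new
            self.mu_acc[:, cols] += acc

    def _adapt_mu(self, batch: int):
        rate = self.mu_acc / batch
        self.mu_step *= np.exp(0.66 * (rate - 0.44))
        np.clip(self.mu_step, 1e-3, 10.0, out=self.mu_step)
        self.mu_acc[:] = 0.0

    # ----- Gaussian blocks ------------------------------------------------
    def _update_theta(self):
        Tm = self.T - 1
        y = (self.mu[:, 1:] - self.rho[:, None] - self.omega[None, :]).ravel()
        X = np.column_stack([
            np.ones(self.I * Tm),
            self.mu[:, :-1].ravel(),
            np.repeat(self.H, Tm, axis=0),
            self.ee[:, :-1].ravel(),
        ])
        XtX = X.T @ X
        L = linalg.cholesky(XtX + 1e-10 * np.eye(XtX.shape[0]), lower=True)
        mean = linalg.cho_solve((L, True), X.T @ y)
        z = self.rng.standard_normal(len(mean))
        theta = mean + self.sigma_e * linalg.solve_triangular(L, z, lower=True, trans="T")
        self.alpha = float(theta[0])
        self.lam = float(theta[1])
        self.beta = theta[2:-1].copy()
        self.beta6 = float(theta[-1])

    def _resid(self, with_rho=True, with_omega=True):
        h = self.H @ self.beta
        pred = (
            self.alpha + self.lam * self.mu[:, :-1] + h[:, None]
            + self.beta6 * self.ee[:, :-1]
        )
        if with_rho:
            pred = pred + self.rho[:, None]
        if with_omega:
            pred = pred + self.omega[None, :]
        return self.mu[:, 1:] - pred

    def _update_rho(self):
        s = self._resid(with_rho=False).sum(axis=1)
        P = np.diag(self.k) - self.gamma * self.W
        Q = P / self.sigma_rho**2 + np.eye(self.I) * (self.T - 1) / self.sigma_e**2
        L = linalg.cholesky(Q, lower=True)
        mean = linalg.cho_solve((L, True), s / self.sigma_e**2)
        z = self.rng.standard_normal(self.I)
        self.rho = mean + linalg.solve_triangular(L, z, lower=True, trans="T")

    def _update_omega(self):
        r = self._resid(with_omega=False).sum(axis=0)
        prec = self.I / self.sigma_e**2 + 1.0 / self.sigma_omega**2
        mean = (r / self.sigma_e**2) / prec
        self.omega = mean + self.rng.standard_normal(self.T - 1) / math.sqrt(prec)

    def _recenter(self):
        # shift mass between alpha and mean(rho): likelihood-invariant
        u = self.rng.normal(0, 0.1)
        P = np.diag(self.k) - self.gamma * self.W
        rho_p = self.rho - u
        dlp = -(rho_p @ P @ rho_p - self.rho @ P @ self.rho) / (2 * self.sigma_rho**2)
        if math.log(self.rng.uniform()) < dlp:
            self.rho = rho_p
            self.alpha += u
        # same for mean(omega)
        u = self.rng.normal(0, 0.1)
        om_p = self.omega - u
        dlp = -(np.sum(om_p**2) - np.sum(self.omega**2)) / (2 * self.sigma_omega**2)
        if math.log(self.rng.uniform()) < dlp:
            self.omega = om_p
            self.alpha += u

    # ----- scale parameters and gamma ------------------------------------
    def _update_scales(self):
        rng = self.rng
        n_e = self.I * (self.T - 1)
        SS_e = float(np.sum(self._resid() ** 2))
        self.sigma_e = math.exp(_slice_sample(
            math.log(self.sigma_e),
            lambda u: (1 - n_e) * u - SS_e * math.exp(-2 * u) / 2,
            rng,
        ))
        SS_o = float(np.sum(self.omega**2))
        n_o = self.T - 1
        s2 = 2 * HALF_NORMAL_SCALE**2
        self.sigma_omega = math.exp(_slice_sample(
            math.log(self.sigma_omega),
            lambda u: (1 - n_o) * u - SS_o * math.exp(-2 * u) / 2 - math.exp(2 * u) / s2,
            rng,
        ))
        SS_1 = float(np.sum(self.mu[:, 0] ** 2))
        self.sigma_1 = math.exp(_slice_sample(
            math.log(self.sigma_1),
            lambda u: (1 - self.I) * u - SS_1 * math.exp(-2 * u) / 2 - math.exp(2 * u) / s2,
            rng,
        ))
        qD = float(self.rho @ (self.k * self.rho))
        qW = float(self.rho @ self.W @ self.rho)
        q = qD - self.gamma * qW
        self.sigma_rho = math.exp(_slice_sample(
            math.log(self.sigma_rho),
            lambda u: (1 - self.I) * u - q * math.exp(-2 * u) / 2,
            rng,
        ))
        eigs = self.car_eigs
        s2rho = self.sigma_rho**2

        def logf_gamma(g):
            if not 1e-9 < g < 1 - 1e-9:
                return -np.inf
            return 0.5 * float(np.sum(np.log1p(-g * eigs))) - (qD - g * qW) / (2 * s2rho)

        self.gamma = _slice_sample(self.gamma, logf_gamma, rng, w=0.3, lower=1e-9, upper=1 - 1e-9)

    # ----- main loop ------------------------------------------------------
    def run(self):
        cfg = self.cfg
        kept = {name: [] for name in ("alpha", "lam", "beta", "beta6", "gamma",
                                      "sigma_rho", "sigma_omega", "sigma_e",
                                      "sigma_1", "rho", "omega", "mu")}
        batch = 50
        for it in range(cfg.iterations):
            self._update_mu()
            if it < cfg.warmup and (it + 1) % batch == 0:
                self._adapt_mu(batch)
            self._update_theta()
            self._update_rho()
            self._update_omega()
            self._recenter()
            self._update_scales()
            if it >= cfg.warmup and (it - cfg.warmup) % cfg.thin == 0:
                kept["alpha"].append(self.alpha)
                kept["lam"].append(self.lam)
                kept["beta"].append(self.beta.copy())
                kept["beta6"].append(self.beta6)
                kept["gamma"].append(self.gamma)
                kept["sigma_rho"].append(self.sigma_rho)
                kept["sigma_omega"].append(self.sigma_omega)
                kept["sigma_e"].append(self.sigma_e)
                kept["sigma_1"].append(self.sigma_1)
                kept["rho"].append(self.rho.copy())
                kept["omega"].append(self.omega.copy())
                kept["mu"].append(self.mu.copy())
        return {k: np.asarray(v) for k, v in kept.items()}


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when any split-Rhat is >= 1.1."""


def fit_mcmc(dataset: RemovalDataset, config: Optional[MCMCConfig] = None) -> PosteriorSamples:
    """Fit the model by MCMC and return retained draws with diagnostics.

    Chains run sequentially from independent substreams of ``config.seed``
    with diffuse random initial values.  Split-Rhat is recorded for every
    scalar parameter; if any is >= 1.1 a ``ConvergenceWarning`` is issued
    and ``samples.converged`` is False (never an error).
    """
    from .diagnostics import compute_rhat

    cfg = config if config is not None else MCMCConfig()
    if not np.all(np.isfinite(dataset.effort[dataset.observed])):
        raise ValueError("non-finite effort values")
    ss = np.random.SeedSequence(cfg.seed)
    chains = []
    for child in ss.spawn(cfg.n_chains):
        runner = _ChainRunner(dataset, cfg, np.random.default_rng(child))
        chains.append(runner.run())

    stacked = {k: np.concatenate([c[k] for c in chains], axis=0) for k in chains[0]}
    rhat = {}
    if cfg.n_chains >= 2 and cfg.kept_per_chain >= 4:
        for name in _SCALAR_PARAMS:
            if name.startswith("beta") and name != "beta6":
                traces = [c["beta"][:, int(name[4:]) - 1] for c in chains]
            else:
                key = {"lambda": "lam"}.get(name, name)
                traces = [c[key] for c in chains]
            rhat[name] = compute_rhat(np.asarray(traces))
    converged = all(r < 1.1 for r in rhat.values()) if rhat else True
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v >= 1.1}
        warnings.warn(f"chains not converged (Rhat >= 1.1): {bad}", ConvergenceWarning)

    return PosteriorSamples(
        alpha=stacked["alpha"], lam=stacked["lam"], beta=stacked["beta"],
        beta6=stacked["beta6"], gamma=stacked["gamma"],
        sigma_rho=stacked["sigma_rho"], sigma_omega=stacked["sigma_omega"],
        sigma_e=stacked["sigma_e"], sigma_1=stacked["sigma_1"],
        rho=stacked["rho"], omega=stacked["omega"], mu=stacked["mu"],
        n_chains=cfg.n_chains, n_warmup=cfg.warmup,
        n_kept=cfg.n_chains * cfg.kept_per_chain, thin=cfg.thin,
        rhat=rhat, converged=converged, seed=cfg.seed,
    )
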