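"""MCMC convergence and model-adequacy diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PosteriorSamples
from .network import RiverNetwork
from .simulate import RemovalDataset


def compute_rhat(chains) -> float:
    """Split potential-scale-reduction factor (Gelman-Rubin R-hat).

    ``chains`` is an (m, n) array (or list of equal-length 1-D traces).
    Each chain is split in half, giving 2m chains of length n//2; R-hat is
    sqrt(((n-1)/n * W + B/n) / W) with W/B the within/between-chain
    variances.  Degenerate all-constant input returns 1.0 by convention.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    if arr.shape[1] < 2:
        raise ValueError("chains must have length >= 2")
    if np.all(arr == arr.flat[0]):
        return 1.0
    if arr.shape[1] >= 4:
        half = arr.shape[1] // 2
        split = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    else:
        split = arr  # too short to split
    n = split.shape[1]
    within = split.var(axis=1, ddof=1).mean()
    between = n * split.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def posterior_predictive_check(samples: PosteriorSamples, dataset: RemovalDataset,
                               seed=None) -> dict:
    """Bayesian P-values for annual total captures.

    For each year, replicate total captures are drawn per posterior draw
    from the Poisson observation model at the sampled latent densities and
    the observed effort; the P-value is P(total_rep >= total_obs) with
    ties counted half.  Values near 0 or 1 flag misfit.
    """
    if samples.mu.shape[1:] != (dataset.n_units, dataset.n_years):
        raise ValueError("samples were not fitted to this dataset")
    rng = np.random.default_rng(seed)
    obs = dataset.observed
    E = np.where(obs, dataset.effort, 0.0)
    totals_obs = np.nansum(np.where(obs, dataset.captures, 0.0), axis=0)
    # sum of independent Poissons is Poisson of the summed mean
    mean_rep = np.einsum("nit,it->nt", np.exp(samples.mu), E)
    totals_rep = rng.poisson(mean_rep)
    greater = (totals_rep > totals_obs[None, :]).mean(axis=0)
    ties = (totals_rep == totals_obs[None, :]).mean(axis=0)
    pvals = greater + 0.5 * ties
    return {year: float(p) for year, p in zip(dataset.years, pvals)}


@dataclass
class ContributionSummary:
    """Relative contribution of measured environmental covariates to
    spatial heterogeneity: delta = V1 / (V1 + V2), where V1 is the
    across-unit variance of the covariate linear predictor H beta and V2
    that of the spatial random effect rho, per posterior draw."""

    delta_draws: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    n_excluded: int


def fixed_effect_contribution(samples: PosteriorSamples, network: RiverNetwork,
                              ci: float = 0.95) -> ContributionSummary:
    """Per-draw delta = V1/(V1+V2) with median and central credible interval.

    Draws with V1 + V2 = 0 (constant predictor and constant field) are
    excluded and counted.
    """
    if samples.rho.shape[1] != network.n_units:
        raise ValueError("samples and network dimensions disagree")
    lin = samples.beta @ network.covariates.T  # (n_draws, I)
    v1 = lin.var(axis=1, ddof=1)
    v2 = samples.rho.var(axis=1, ddof=1)
    tot = v1 + v2
    valid = tot > 0
    delta = v1[valid] / tot[valid]
    if delta.size == 0:
        raise ValueError("delta undefined in every draw (V1 + V2 = 0)")
    a = (1 - ci) / 2
    lo, med, hi = np.quantile(delta, [a, 0.5, 1 - a])
    return ContributionSummary(
        delta_draws=delta, median=float(med), ci_low=float(lo),
        ci_high=float(hi), n_excluded=int(np.sum(~valid)),
    )
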