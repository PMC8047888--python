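"""Proper conditional-autoregressive (CAR) Gaussian field on the river graph.

The spatial random effect rho has conditionals

    rho_i | rho_{-i} ~ Normal(gamma * sum_{j in delta_i} rho_j / k_i,
                              sigma_rho^2 / k_i)

which is the proper CAR model: jointly, rho ~ N(0, sigma_rho^2 (D - gamma W)^{-1})
with D = diag(k_i) and W the 0/1 adjacency.  For gamma in (0, 1) and a
connected graph the precision matrix is positive definite.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .network import RiverNetwork


def car_precision(network: RiverNetwork, gamma: float, sigma_rho: float) -> np.ndarray:
    """Precision matrix (D - gamma W) / sigma_rho^2 of the joint CAR field."""
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must lie in (0, 1); got {gamma}")
    if sigma_rho <= 0:
        raise ValueError("sigma_rho must be positive")
    D = np.diag(network.neighbor_counts)
    W = network.adjacency_matrix
    return (D - gamma * W) / sigma_rho**2


def car_covariance(network: RiverNetwork, gamma: float, sigma_rho: float) -> np.ndarray:
    """Joint covariance sigma_rho^2 (D - gamma W)^{-1}."""
    return linalg.inv(car_precision(network, gamma, sigma_rho))


def sample_car_field(
    network: RiverNetwork,
    gamma: float,
    sigma_rho: float,
    seed=None,
    size: int | None = None,
) -> np.ndarray:
    """Exact joint draw(s) from the proper CAR distribution.

    Draws z ~ N(0, I) and solves L^T x = z with Q = L L^T the Cholesky
    factor of the precision, giving x ~ N(0, Q^{-1}).

    Parameters
    ----------
    seed:
        int seed or an existing ``numpy.random.Generator``.
    size:
        If None, return one field of shape (I,); else shape (size, I).

    Raises
    ------
    ValueError
        If gamma is outside (0, 1) or the precision is not positive
        definite.
    """
    Q = car_precision(network, gamma, sigma_rho)
    try:
        L = linalg.cholesky(Q, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded by gamma check
        raise ValueError("CAR precision matrix is not positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 1 if size is None else int(size)
    z = rng.standard_normal((network.n_units, n))
    x = linalg.solve_triangular(L, z, lower=True, trans="T")
    return x[:, 0] if size is None else x.T
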