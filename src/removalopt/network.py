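"""River-network spatial structure.

The study region is a branching river divided into short sections (the
management units).  Two sections are neighbours when they share an edge of
the river line, which makes the adjacency graph a tree-like, nearly linear
network.  Each unit carries a vector of standardized environmental
covariates (paddy-field area, dry crop fields, slope, flow accumulation,
road density in the motivating application).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

N_COVARIATES = 5

COVARIATE_NAMES = ("paddy", "dry_crop", "slope", "flow_accum", "road")


@dataclass(frozen=True)
class RiverNetwork:
    """Spatial units of a river system with covariates and adjacency.

    Parameters
    ----------
    unit_ids:
        Labels of the I spatial units.  Internal indexing follows this
        order everywhere in the package.
    covariates:
        (I, 5) array of environmental covariates, standardized to mean 0
        and SD 1 per column.
    edges:
        Unordered pairs of unit *indices* sharing a river edge.
    """

    unit_ids: tuple
    covariates: np.ndarray
    edges: tuple

    def __post_init__(self):
        ids = tuple(str(u) for u in self.unit_ids)
        object.__setattr__(self, "unit_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit ids")
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != len(ids):
            raise ValueError(
                f"covariates must be (n_units, k); got {cov.shape} for {len(ids)} units"
            )
        object.__setattr__(self, "covariates", cov)
        I = len(ids)
        edges = []
        seen = set()
        for a, b in self.edges:
            a, b = int(a), int(b)
            if a == b:
                raise ValueError(f"self-edge at unit index {a}")
            if not (0 <= a < I and 0 <= b < I):
                raise ValueError(f"edge ({a},{b}) out of range for {I} units")
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                edges.append(key)
        object.__setattr__(self, "edges", tuple(sorted(edges)))
        k = self.neighbor_counts
        if np.any(k < 1):
            isolated = [ids[i] for i in np.where(k < 1)[0]]
            raise ValueError(f"isolated units (k_i = 0) not allowed: {isolated}")
        if not nx.is_connected(self.graph):
            raise ValueError("adjacency graph must be connected")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_units))
        g.add_edges_from(self.edges)
        return g

    @property
    def adjacency_matrix(self) -> np.ndarray:
        """Symmetric 0/1 neighbour indicator W (no self-loops)."""
        W = np.zeros((self.n_units, self.n_units))
        for a, b in self.edges:
            W[a, b] = W[b, a] = 1.0
        return W

    @property
    def neighbor_counts(self) -> np.ndarray:
        """k_i = number of neighbours of each unit."""
        k = np.zeros(self.n_units)
        for a, b in self.edges:
            k[a] += 1
            k[b] += 1
        return k

    @property
    def neighbor_sets(self) -> list:
        """delta_i = set of neighbour indices per unit."""
        out = [set() for _ in range(self.n_units)]
        for a, b in self.edges:
            out[a].add(b)
            out[b].add(a)
        return out

    def index_of(self, unit_id: str) -> int:
        return self.unit_ids.index(str(unit_id))


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to (population) SD 1, column-wise."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column cannot be standardized")
    return (x - x.mean(axis=0)) / sd


def generate_river_network(
    n_units: int,
    branching: float = 0.15,
    seed: int | None = None,
    n_covariates: int = N_COVARIATES,
) -> RiverNetwork:
    """Generate a random chain-with-branches river network.

    The network is grown as a random tree: each new section extends the
    current downstream tip with probability ``1 - branching`` and otherwise
    branches off a uniformly chosen existing section (a confluence).  With
    ``branching = 0`` the result is a pure chain, matching a single
    unbranched river.  Covariates are drawn iid standard normal and then
    re-standardized column-wise so tests can assert exact mean-0 / SD-1.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    if not 0.0 <= branching <= 1.0:
        raise ValueError("branching must be a probability")
    rng = np.random.default_rng(seed)
    edges = []
    tip = 0
    for j in range(1, n_units):
        if branching > 0 and rng.random() < branching:
            parent = int(rng.integers(0, j))
        else:
            parent = tip
        edges.append((parent, j))
        tip = j
    cov = standardize_columns(rng.standard_normal((n_units, n_covariates)))
    unit_ids = tuple(f"u{i + 1}" for i in range(n_units))
    return RiverNetwork(unit_ids=unit_ids, covariates=cov, edges=tuple(edges))
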