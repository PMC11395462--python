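"""Topology-based protein scoring on the interaction network.

Four complementary algorithms score every protein by how strongly it is
topologically associated with a seed set (disorder biomarkers):

* **network propagation** — global diffusion to the fixed point of
  ``F_t = alpha * W' * F_{t-1} + (1 - alpha) * Y`` with the degree-symmetric
  normalization ``w'_ij = a_ij / sqrt(deg_i * deg_j)``;
* **random walk with restart** — stationary visiting probability of
  ``p_t = (1 - r) * W * p_{t-1} + r * p0`` with column-stochastic ``W`` and
  ``p0`` uniform over the seeds;
* **interconnectivity** — local degree-normalized score combining direct
  adjacency and shared-neighbor counts, averaged over the seeds;
* **neighborhood scoring** — one-step convex smoothing of a node-level
  signal over direct neighbors.

All four operate on the undirected simple graph; node order is the sorted
node list, and results come back as pandas Series indexed by node id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PropagationParams",
    "RWRParams",
    "NeighborhoodParams",
    "ConvergenceError",
    "network_propagation",
    "random_walk_restart",
    "interconnectivity_score",
    "neighborhood_score",
]


class ConvergenceError(RuntimeError):
    """Iteration failed to reach the fixed point within ``max_iter``."""

    def __init__(self, method: str, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"{method} did not converge in {iterations} iterations "
            f"(max-norm residual {residual:.3e})"
        )


@dataclass(frozen=True)
class PropagationParams:
    alpha: float = 0.8  # weight on the diffused flow vs the prior
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class RWRParams:
    restart: float = 0.75  # probability of teleporting back to the seeds
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError("restart must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class NeighborhoodParams:
    alpha: float = 0.5  # weight on a node's own level vs its neighbor mean

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


def _node_order(graph: nx.Graph) -> list:
    return sorted(graph.nodes)


def _adjacency(graph: nx.Graph, nodes: list) -> sp.csr_matrix:
    return nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr", dtype=float)


def _seed_vector(nodes: list, seeds: Iterable) -> np.ndarray:
    seeds = set(seeds)
    unknown = seeds - set(nodes)
    if unknown:
        raise KeyError(f"seed nodes not in graph: {sorted(unknown)[:5]}")
    index = {node: i for i, node in enumerate(nodes)}
    y = np.zeros(len(nodes))
    for s in seeds:
        y[index[s]] = 1.0
    return y


def network_propagation(
    graph: nx.Graph, seeds: Iterable, params: PropagationParams = PropagationParams()
) -> pd.Series:
    """Diffuse unit flow from the seed nodes to its network-wide fixed point.

    The converged flow measures each node's overall proximity to all seeds.
    Empty seed sets yield the all-zero vector with a warning. Since the
    symmetric normalization has spectral radius <= 1 and alpha < 1, the
    iteration is a contraction; non-convergence raises ``ConvergenceError``.
    """
    nodes = _node_order(graph)
    y = _seed_vector(nodes, seeds)
    if y.sum() == 0:
        warnings.warn("empty seed set: propagation returns zeros", stacklevel=2)
        return pd.Series(y, index=nodes)
    adj = _adjacency(graph, nodes)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    d_half = sp.diags(inv_sqrt)
    w_norm = d_half @ adj @ d_half
    f = y.copy()
    residual = np.inf
    for _ in range(params.max_iter):
        f_next = params.alpha * (w_norm @ f) + (1.0 - params.alpha) * y
        residual = float(np.max(np.abs(f_next - f)))
        f = f_next
        if residual < params.tol:
            return pd.Series(np.maximum(f, 0.0), index=nodes)
    raise ConvergenceError("network propagation", params.max_iter, residual)


def random_walk_restart(
    graph: nx.Graph, seeds: Iterable, params: RWRParams = RWRParams()
) -> pd.Series:
    """Stationary distribution of a random walk that restarts at the seeds.

    The transition matrix is column-stochastic (a_ij / deg_j); a degree-0
    node's column is the identity (self-absorbing), which preserves
    stochasticity. The converged probabilities sum to 1.
    """
    nodes = _node_order(graph)
    y = _seed_vector(nodes, seeds)
    if y.sum() == 0:
        warnings.warn("empty seed set: random walk returns zeros", stacklevel=2)
        return pd.Series(y, index=nodes)
    p0 = y / y.sum()
    adj = _adjacency(graph, nodes)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    inv_deg = np.zeros_like(deg)
    nz = deg > 0
    inv_deg[nz] = 1.0 / deg[nz]
    w = adj @ sp.diags(inv_deg)  # column-stochastic on non-isolated columns
    if (~nz).any():  # self-loop on isolated nodes keeps columns stochastic
        w = w + sp.diags((~nz).astype(float))
    w = w.tocsr()
    p = p0.copy()
    residual = np.inf
    for _ in range(params.max_iter):
        p_next = (1.0 - params.restart) * (w @ p) + params.restart * p0
        residual = float(np.max(np.abs(p_next - p)))
        p = p_next
        if residual < params.tol:
            return pd.Series(p, index=nodes)
    raise ConvergenceError("random walk with restart", params.max_iter, residual)


def interconnectivity_score(graph: nx.Graph, seeds: Iterable) -> pd.Series:
    """Mean interconnectivity of every node to the seed set.

    ``ICN(i, j) = (2 * e(i, j) + n(i, j)) / sqrt(deg_i * deg_j)`` where
    e(i, j) indicates a direct edge and n(i, j) counts shared neighbors; the
    degree normalization removes hub bias. Pairs with a degree-0 member
    contribute 0. ``Score(i)`` is the mean of ICN(i, j) over seed nodes j.
    """
    nodes = _node_order(graph)
    y = _seed_vector(nodes, seeds)
    seed_idx = np.flatnonzero(y)
    if seed_idx.size == 0:
        warnings.warn("empty seed set: interconnectivity returns zeros", stacklevel=2)
        return pd.Series(np.zeros(len(nodes)), index=nodes)
    adj = _adjacency(graph, nodes)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    shared = (adj @ adj[:, seed_idx]).toarray()  # n(i, j) for seed columns
    direct = adj[:, seed_idx].toarray()
    numer = 2.0 * direct + shared
    denom = np.sqrt(np.outer(deg, deg[seed_idx]))
    with np.errstate(divide="ignore", invalid="ignore"):
        icn = np.where(denom > 0, numer / denom, 0.0)
    return pd.Series(icn.mean(axis=1), index=nodes)


def neighborhood_score(
    graph: nx.Graph,
    seed_levels: Mapping | pd.Series | Iterable,
    params: NeighborhoodParams = NeighborhoodParams(),
) -> pd.Series:
    """Convex one-step smoothing of a node signal over direct neighbors.

    ``FC'_i = alpha * FC_i + (1 - alpha) * mean_j FC_j`` over the neighbors
    j of i. ``seed_levels`` is either a full node -> level mapping or an
    iterable of seed nodes given level 1 (others 0). A degree-0 node keeps
    ``alpha * FC_i`` (its neighbor mean is empty, contributing nothing).
    """
    nodes = _node_order(graph)
    if isinstance(seed_levels, (Mapping, pd.Series)):
        fc = np.array([float(seed_levels.get(n, 0.0)) for n in nodes]) \
            if isinstance(seed_levels, Mapping) \
            else pd.Series(seed_levels).reindex(nodes).fillna(0.0).to_numpy(dtype=float)
    else:
        fc = _seed_vector(nodes, seed_levels)
    adj = _adjacency(graph, nodes)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    neigh_sum = adj @ fc
    neigh_mean = np.divide(neigh_sum, deg, out=np.zeros_like(neigh_sum), where=deg > 0)
    smoothed = params.alpha * fc + (1.0 - params.alpha) * neigh_mean
    return pd.Series(smoothed, index=nodes)
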