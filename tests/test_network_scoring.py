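"""Network scoring: fixed-point oracles, conservation laws and hand values."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mclprio.network_scoring import (
    ConvergenceError,
    NeighborhoodParams,
    PropagationParams,
    RWRParams,
    interconnectivity_score,
    neighborhood_score,
    network_propagation,
    random_walk_restart,
)
from tests.conftest import random_graph


def propagation_linear_solve(graph: nx.Graph, seeds, alpha: float) -> pd.Series:
    """Closed-form oracle F = (1 - alpha)(I - alpha W')^{-1} Y."""
    nodes = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    deg = a.sum(axis=1)
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    w = np.diag(inv_sqrt) @ a @ np.diag(inv_sqrt)
    y = np.array([1.0 if v in set(seeds) else 0.0 for v in nodes])
    f = (1 - alpha) * np.linalg.solve(np.eye(len(nodes)) - alpha * w, y)
    return pd.Series(f, index=nodes)


def rwr_linear_solve(graph: nx.Graph, seeds, r: float) -> pd.Series:
    """Closed-form oracle p = r (I - (1 - r) W)^{-1} p0."""
    nodes = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    deg = a.sum(axis=0)
    w = np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)
    for j in np.flatnonzero(deg == 0):
        w[j, j] = 1.0
    y = np.array([1.0 if v in set(seeds) else 0.0 for v in nodes])
    p0 = y / y.sum()
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * w, p0)
    return pd.Series(p, index=nodes)


def icn_brute_force(graph: nx.Graph, seeds) -> pd.Series:
    """Direct shared-neighbor enumeration oracle."""
    seeds = sorted(seeds)
    scores = {}
    for i in graph.nodes:
        total = 0.0
        for j in seeds:
            di, dj = graph.degree[i], graph.degree[j]
            if di == 0 or dj == 0:
                continue
            e = 1.0 if graph.has_edge(i, j) else 0.0
            shared = len(set(graph[i]) & set(graph[j]))
            total += (2 * e + shared) / np.sqrt(di * dj)
        scores[i] = total / len(seeds)
    return pd.Series(scores).sort_index()


def seeds_for(graph: nx.Graph, rng: np.random.Generator, k: int = 3) -> list:
    nodes = sorted(graph.nodes)
    return [nodes[i] for i in rng.choice(len(nodes), size=min(k, len(nodes)), replace=False)]


class TestPropagation:
    @pytest.mark.parametrize("seed", range(10))
    def test_iterative_matches_linear_solve(self, seed):
        g = random_graph(seed)
        rng = np.random.default_rng(seed)
        seeds = seeds_for(g, rng)
        got = network_propagation(g, seeds, PropagationParams(alpha=0.8, tol=1e-10))
        want = propagation_linear_solve(g, seeds, 0.8)
        assert np.max(np.abs(got - want)) < 1e-6

    def test_alpha_zero_returns_prior_exactly(self):
        g = nx.path_graph(5)
        got = network_propagation(g, [1], PropagationParams(alpha=0.0))
        assert list(got) == [0.0, 1.0, 0.0, 0.0, 0.0]

    def test_empty_seed_set_returns_zeros_with_warning(self):
        g = nx.path_graph(4)
        with pytest.warns(UserWarning, match="empty seed"):
            got = network_propagation(g, [])
        assert (got == 0.0).all()

    def test_positive_alpha_reaches_every_connected_node(self):
        g = nx.path_graph(6)
        got = network_propagation(g, [0], PropagationParams(alpha=0.8))
        assert (got > 0).all()

    def test_non_convergence_raises_with_iteration_count(self):
        g = nx.path_graph(50)
        with pytest.raises(ConvergenceError, match="2 iterations"):
            network_propagation(g, [0], PropagationParams(alpha=0.9, tol=1e-14, max_iter=2))

    def test_unknown_seed_raises(self):
        with pytest.raises(KeyError):
            network_propagation(nx.path_graph(3), [99])


class TestRandomWalkRestart:
    @pytest.mark.parametrize("seed", range(10))
    def test_iterative_matches_linear_solve(self, seed):
        g = random_graph(seed + 100)
        rng = np.random.default_rng(seed)
        seeds = seeds_for(g, rng)
        got = random_walk_restart(g, seeds, RWRParams(restart=0.75, tol=1e-12))
        want = rwr_linear_solve(g, seeds, 0.75)
        assert np.max(np.abs(got - want)) < 1e-6

    def test_probability_mass_conserved(self):
        g = random_graph(7)
        got = random_walk_restart(g, seeds_for(g, np.random.default_rng(7)))
        assert got.sum() == pytest.approx(1.0, abs=1e-10)

    def test_mass_conserved_with_isolated_node(self):
        g = nx.path_graph(4)
        g.add_node(99)  # degree-0: self-absorbing column
        got = random_walk_restart(g, [0, 99])
        assert got.sum() == pytest.approx(1.0, abs=1e-10)
        assert got[99] > 0

    def test_restart_one_returns_seed_distribution(self):
        g = nx.path_graph(5)
        got = random_walk_restart(g, [0, 2], RWRParams(restart=1.0))
        assert list(got) == [0.5, 0.0, 0.5, 0.0, 0.0]


class TestInterconnectivity:
    def test_triangle_hand_value(self):
        g = nx.complete_graph(3)  # triangle a=0, b=1, c=2
        got = interconnectivity_score(g, [1])
        # ICN(a, b) = (2*1 + 1) / sqrt(2*2) = 1.5
        assert got[0] == pytest.approx(1.5)
        assert got[2] == pytest.approx(1.5)

    def test_non_adjacent_pair_without_shared_neighbors_scores_zero(self):
        g = nx.Graph([(0, 1), (2, 3)])
        got = interconnectivity_score(g, [0])
        assert got[2] == 0.0 and got[3] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        g = random_graph(seed + 200, n_max=50)
        rng = np.random.default_rng(seed)
        seeds = seeds_for(g, rng)
        got = interconnectivity_score(g, seeds)
        want = icn_brute_force(g, seeds)
        assert np.max(np.abs(got - want)) < 1e-12

    def test_pairwise_symmetry(self):
        g = random_graph(42, n_max=40)
        for i in list(g.nodes)[:10]:
            for j in list(g.nodes)[:10]:
                si = interconnectivity_score(g, [j])[i]
                sj = interconnectivity_score(g, [i])[j]
                assert si == pytest.approx(sj, abs=1e-12)


class TestNeighborhood:
    def test_isolated_signal_node_keeps_alpha_fraction(self):
        g = nx.star_graph(3)
        got = neighborhood_score(g, {0: 1.0}, NeighborhoodParams(alpha=0.5))
        assert got[0] == pytest.approx(0.5)

    def test_constant_field_is_a_fixed_point(self):
        g = random_graph(9, n_max=60)
        g.remove_nodes_from(list(nx.isolates(g)))
        fc = {v: 0.7 for v in g.nodes}
        got = neighborhood_score(g, fc, NeighborhoodParams(alpha=0.5))
        assert np.allclose(got, 0.7)

    def test_star_center_hand_value(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        got = neighborhood_score(g, {1: 1.0, 2: 1.0}, NeighborhoodParams(alpha=0.5))
        assert got[0] == pytest.approx(0.25)  # 0.5*0 + 0.5*(2/4)


class TestPermutationEquivariance:
    @pytest.mark.parametrize(
        "scorer",
        [
            lambda g, s: network_propagation(g, s),
            lambda g, s: random_walk_restart(g, s),
            lambda g, s: interconnectivity_score(g, s),
            lambda g, s: neighborhood_score(g, s),
        ],
        ids=["propagation", "rwr", "icn", "neighborhood"],
    )
    def test_relabeling_permutes_scores(self, scorer):
        g = random_graph(5, n_max=40)
        rng = np.random.default_rng(5)
        seeds = seeds_for(g, rng)
        nodes = sorted(g.nodes)
        mapping = {v: 1000 + i for i, v in enumerate(rng.permutation(nodes))}
        h = nx.relabel_nodes(g, mapping)
        base = scorer(g, seeds)
        permuted = scorer(h, [mapping[s] for s in seeds])
        for v in nodes:
            assert permuted[mapping[v]] == pytest.approx(base[v], abs=1e-9)
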