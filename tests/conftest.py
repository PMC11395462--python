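"""Shared fixtures: small synthetic knowledge bases and toy graphs."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from mclprio.kb_model import (
    DisorderAnnotation,
    Effect,
    GeneSet,
    GeneSetKind,
    Interaction,
    KnowledgeBase,
    LinearPathway,
    Mechanism,
    Protein,
    TargetStatus,
)
from mclprio.synthetic_kb import SynthConfig, generate_kb

SMALL_SYNTH = SynthConfig(
    n_proteins=600,
    n_disorders=6,
    module_size=40,
    n_shared_targets=20,
    n_pathway_maps=40,
    n_metaminer_pathways=12,
    n_linear_pathways=60,
    n_similar_diseases=8,
    n_similar_noise=3,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def small_kb_truth():
    """Down-scaled synthetic knowledge base shared across test modules."""
    return generate_kb(SMALL_SYNTH)


@pytest.fixture(scope="session")
def small_kb(small_kb_truth):
    return small_kb_truth[0]


@pytest.fixture()
def tiny_kb() -> KnowledgeBase:
    """Hand-built 8-protein knowledge base with one annotated disorder.

    Network: path 1-2-3-4 plus triangle 5-6-7; protein 8 isolated.
    Disorder 'd' has biomarkers {2, 5} and targets {3, 6}.
    """
    proteins = {i: Protein(i, f"G{i}") for i in range(1, 9)}
    edges = [(1, 2), (2, 3), (3, 4), (5, 6), (6, 7), (5, 7)]
    interactions = [
        Interaction(a, b, Effect.activation, Mechanism.binding) for a, b in edges
    ]
    biomarkers = GeneSet("d__biomarkers", frozenset({2, 5}), GeneSetKind.biomarker_set)
    targets = GeneSet("d__targets", frozenset({3, 6}), GeneSetKind.target_set)
    ann = DisorderAnnotation(
        "d",
        biomarkers,
        targets,
        {3: TargetStatus.validated, 6: TargetStatus.candidate},
    )
    kb = KnowledgeBase(
        proteins=proteins,
        interactions=interactions,
        pathway_maps=[
            GeneSet("pm1", frozenset({2, 3, 4}), GeneSetKind.pathway_map),
            GeneSet("pm2", frozenset({5, 6, 7, 8}), GeneSetKind.pathway_map),
        ],
        metaminer_pathways=[
            GeneSet("mm1", frozenset({1, 2, 3}), GeneSetKind.metaminer_pathway),
            GeneSet("mm2", frozenset({3, 6}), GeneSetKind.metaminer_pathway),
        ],
        linear_pathways=[
            LinearPathway("lp1", (1, 2, 3)),
            LinearPathway("lp2", (3, 4)),
            LinearPathway("lp3", (5, 6, 7)),
        ],
        disorder_annotations={"d": ann},
    )
    kb.validate()
    return kb


def random_graph(seed: int, n_max: int = 200) -> nx.Graph:
    """Random connected-ish graph for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, n_max + 1))
    p = float(rng.uniform(0.02, 0.15))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    return g
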