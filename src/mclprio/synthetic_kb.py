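"""Synthetic knowledge bases with planted ground truth.

The real inputs to the pipeline are proprietary curated databases, so every
downstream stage is exercised on generated knowledge bases that emulate the
statistical structure the analysis assumes:

* a scale-free interactome (preferential attachment), because curated
  protein-interaction networks are heavy-tailed;
* one topological module per disorder (BFS-grown from a random node), inside
  which biomarkers and drug targets cluster — this creates the
  guilt-by-association signal the network scorers presume;
* a planted set of shared targets attached to >= 2 disorders: exactly the
  positive-control definition, so parameter-recovery tests have ground truth;
* pathway maps and consortium pathways mixing module-derived and random
  members; linear signaling chains partly seeded at biomarkers;
* candidate similar-disease target sets sampled from the pooled disorder
  targets (guaranteeing the >= 3 shared-target selection rule is
  exercisable) plus pure-noise candidates.

Generation is fully deterministic under a fixed seed: identical configs
serialize to byte-identical directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .kb_model import (
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

__all__ = ["SynthConfig", "SyntheticTruth", "generate_kb", "define_positive_controls"]

_DISORDER_NAMES = [
    "alzheimers_disease",
    "anorexia_nervosa",
    "anxiety",
    "bipolar_disorder",
    "bulimia",
    "depression",
    "mania",
    "obsessive_compulsive_disorder",
    "parkinsons_disease",
    "pathological_gambling",
    "phobic_disorders",
    "post_traumatic_stress_disorder",
    "schizophrenia",
]

_EFFECTS = [Effect.activation, Effect.inhibition, Effect.unspecified]
_MECHANISMS = [
    Mechanism.binding,
    Mechanism.phosphorylation,
    Mechanism.cleavage,
    Mechanism.transport,
    Mechanism.catalysis,
    Mechanism.covalent_modification,
]
_STATUSES = [TargetStatus.validated, TargetStatus.candidate, TargetStatus.exploratory]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generated knowledge base.

    Defaults describe a down-scaled but structurally faithful knowledge
    base: 2000 proteins, 13 disorder modules of 80 proteins each, 50 planted
    multi-indication targets.
    """

    n_proteins: int = 2000
    ba_attachment: int = 3  # preferential-attachment edges per new node
    n_disorders: int = 13
    module_size: int = 80
    biomarker_rate: float = 0.3  # fraction of a module annotated as biomarkers
    biomarker_noise: int = 5  # background biomarkers per disorder
    target_rate: float = 0.15  # fraction of a module annotated as (unique) targets
    n_shared_targets: int = 50  # planted >= 2-indication positives
    n_pathway_maps: int = 120
    pathway_size_range: tuple[int, int] = (10, 40)
    pathway_signal_fraction: float = 0.6  # members drawn from a disorder module
    n_metaminer_pathways: int = 30
    n_linear_pathways: int = 150
    chain_length_range: tuple[int, int] = (3, 8)
    n_similar_diseases: int = 15  # eligible candidates (>= min shared targets)
    n_similar_noise: int = 5  # ineligible noise candidates
    similar_shared_range: tuple[int, int] = (3, 8)  # planted positives per candidate
    similar_extra_targets: int = 5  # non-positive disorder targets per candidate
    similar_noise_members: int = 8  # random members per candidate
    rng_seed: int = 7

    def validate(self) -> None:
        if self.n_proteins < self.n_disorders * 10:
            raise ValueError("n_proteins too small for the requested disorders")
        if self.module_size > self.n_proteins:
            raise ValueError("module_size exceeds the protein universe")
        if self.n_disorders < 2 and self.n_shared_targets > 0:
            raise ValueError("shared targets need at least 2 disorders")
        n_unique = self.n_disorders * max(1, round(self.target_rate * self.module_size))
        if self.n_shared_targets + n_unique > self.n_proteins // 2:
            raise ValueError(
                "infeasible config: too many targets for the protein universe"
            )
        if self.ba_attachment < 1 or self.ba_attachment >= self.n_proteins:
            raise ValueError("invalid preferential-attachment parameter")


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    planted_targets: frozenset[int]
    module_membership: dict[str, frozenset[int]]
    # evidence channels carrying planted signal (vs pure noise)
    informative_features: dict[str, bool] = field(default_factory=dict)


def define_positive_controls(kb: KnowledgeBase) -> frozenset[int]:
    """Proteins present (any development status) in >= 2 disorders' target sets."""
    counts: dict[int, int] = {}
    for ann in kb.disorder_annotations.values():
        for pid in ann.targets.members:
            counts[pid] = counts.get(pid, 0) + 1
    return frozenset(pid for pid, c in counts.items() if c >= 2)


def _grow_module(graph: nx.Graph, start: int, size: int, rng: np.random.Generator) -> list[int]:
    """BFS from ``start`` until ``size`` nodes are collected (deterministic
    neighbor order), topping up with random nodes if the component is small."""
    seen = {start}
    frontier = [start]
    order = [start]
    while frontier and len(order) < size:
        nxt: list[int] = []
        for node in frontier:
            for nb in sorted(graph[node]):
                if nb not in seen:
                    seen.add(nb)
                    order.append(nb)
                    nxt.append(nb)
                    if len(order) >= size:
                        return order
        frontier = nxt
    if len(order) < size:
        rest = sorted(set(graph.nodes) - seen)
        extra = rng.choice(len(rest), size=size - len(order), replace=False)
        order.extend(rest[i] for i in sorted(extra))
    return order


def _sample(rng: np.random.Generator, pool: Iterable[int], k: int) -> list[int]:
    pool = sorted(pool)
    if k >= len(pool):
        return pool
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_kb(config: SynthConfig = SynthConfig()) -> tuple[KnowledgeBase, SyntheticTruth]:
    """Generate a knowledge base and its planted truth.

    The planted >= 2-indication target set has exactly
    ``config.n_shared_targets`` members and coincides with
    ``define_positive_controls`` on the generated knowledge base.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    n = config.n_proteins
    proteins = {pid: Protein(pid, f"GENE{pid}") for pid in range(1, n + 1)}
    ids = sorted(proteins)

    # -- interactome: preferential attachment, relabeled to 1-based ids
    ba_seed = int(rng.integers(0, 2**31 - 1))
    raw = nx.barabasi_albert_graph(n, config.ba_attachment, seed=ba_seed)
    graph = nx.relabel_nodes(raw, {i: i + 1 for i in range(n)})
    interactions = [
        Interaction(
            min(a, b),
            max(a, b),
            _EFFECTS[rng.integers(0, len(_EFFECTS))],
            _MECHANISMS[rng.integers(0, len(_MECHANISMS))],
        )
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges)
    ]

    disorders = [_DISORDER_NAMES[i % len(_DISORDER_NAMES)] + ("" if i < 13 else f"_{i}")
                 for i in range(config.n_disorders)]

    # -- disorder modules
    starts = _sample(rng, ids, config.n_disorders)
    modules: dict[str, list[int]] = {}
    for disorder, start in zip(disorders, starts):
        modules[disorder] = _grow_module(graph, start, config.module_size, rng)

    # -- biomarkers: in-module enrichment plus background noise
    biomarkers: dict[str, set[int]] = {}
    for disorder in disorders:
        n_in = max(1, round(config.biomarker_rate * config.module_size))
        chosen = set(_sample(rng, modules[disorder], n_in))
        chosen |= set(_sample(rng, set(ids) - chosen, config.biomarker_noise))
        biomarkers[disorder] = chosen

    # -- targets: planted shared (>= 2 indications) plus disorder-unique
    assigned: dict[int, set[str]] = {}
    module_pool = sorted(set().union(*(set(m) for m in modules.values())))
    shared = _sample(rng, module_pool, config.n_shared_targets)
    if len(shared) < config.n_shared_targets:
        raise ValueError("infeasible config: modules too small for shared targets")
    for pid in shared:
        homes = [d for d in disorders if pid in set(modules[d])]
        first = homes[rng.integers(0, len(homes))] if homes else disorders[
            rng.integers(0, len(disorders))
        ]
        others = [d for d in disorders if d != first]
        n_extra = 1 + (1 if rng.random() < 0.2 else 0)
        extra = [others[i] for i in sorted(rng.choice(len(others), size=n_extra, replace=False))]
        assigned[pid] = {first, *extra}
    used = set(shared)
    unique_targets: dict[str, set[int]] = {d: set() for d in disorders}
    n_unique = max(1, round(config.target_rate * config.module_size))
    for disorder in disorders:
        pool = set(modules[disorder]) - used
        chosen = set(_sample(rng, pool, n_unique))
        unique_targets[disorder] = chosen
        used |= chosen

    annotations: dict[str, DisorderAnnotation] = {}
    for disorder in disorders:
        targets = unique_targets[disorder] | {
            pid for pid, ds in assigned.items() if disorder in ds
        }
        status = {
            pid: _STATUSES[rng.integers(0, len(_STATUSES))] for pid in sorted(targets)
        }
        annotations[disorder] = DisorderAnnotation(
            disorder=disorder,
            biomarkers=GeneSet(
                f"{disorder}__biomarkers",
                frozenset(biomarkers[disorder]),
                GeneSetKind.biomarker_set,
            ),
            targets=GeneSet(
                f"{disorder}__targets", frozenset(targets), GeneSetKind.target_set
            ),
            target_status=status,
        )

    # -- pathway maps: module-derived members mixed with random background
    pathway_maps: list[GeneSet] = []
    lo, hi = config.pathway_size_range
    for i in range(config.n_pathway_maps):
        size = int(rng.integers(lo, hi + 1))
        disorder = disorders[rng.integers(0, len(disorders))]
        n_signal = round(config.pathway_signal_fraction * size)
        members = set(_sample(rng, modules[disorder], n_signal))
        members |= set(_sample(rng, set(ids) - members, size - len(members)))
        kind = (
            GeneSetKind.disease_pathway_map if i % 2 else GeneSetKind.pathway_map
        )
        pathway_maps.append(GeneSet(f"map_{i:04d}", frozenset(members), kind))

    # -- consortium pathways: same construction, smaller collection
    metaminer: list[GeneSet] = []
    for i in range(config.n_metaminer_pathways):
        size = int(rng.integers(lo, hi + 1))
        disorder = disorders[rng.integers(0, len(disorders))]
        n_signal = round(config.pathway_signal_fraction * size)
        members = set(_sample(rng, modules[disorder], n_signal))
        members |= set(_sample(rng, set(ids) - members, size - len(members)))
        metaminer.append(GeneSet(f"mm_{i:03d}", frozenset(members), GeneSetKind.metaminer_pathway))

    # -- linear chains: random simple paths, half started at a biomarker so
    #    the biomarker-co-occurrence ratio carries signal
    all_biomarkers = sorted(set().union(*biomarkers.values()))
    chains: list[LinearPathway] = []
    clo, chi_ = config.chain_length_range
    attempts = 0
    while len(chains) < config.n_linear_pathways and attempts < config.n_linear_pathways * 20:
        attempts += 1
        length = int(rng.integers(clo, chi_ + 1))
        if rng.random() < 0.5 and all_biomarkers:
            start = all_biomarkers[rng.integers(0, len(all_biomarkers))]
        else:
            start = ids[rng.integers(0, len(ids))]
        path = [start]
        while len(path) < length:
            nbrs = [nb for nb in sorted(graph[path[-1]]) if nb not in path]
            if not nbrs:
                break
            path.append(nbrs[rng.integers(0, len(nbrs))])
        if len(path) >= 2:
            chains.append(LinearPathway(f"lp_{len(chains):04d}", tuple(path)))

    # -- similar-disease candidates
    pooled_targets = sorted(
        set().union(*(ann.targets.members for ann in annotations.values()))
    )
    non_shared_pool = sorted(set(pooled_targets) - set(shared))
    similar: list[GeneSet] = []
    slo, shi = config.similar_shared_range
    for i in range(config.n_similar_diseases):
        n_shared_i = int(rng.integers(slo, shi + 1))
        members = set(_sample(rng, shared, n_shared_i))
        members |= set(_sample(rng, non_shared_pool, config.similar_extra_targets))
        members |= set(
            _sample(rng, set(ids) - members, config.similar_noise_members)
        )
        similar.append(
            GeneSet(f"simdis_{i:02d}", frozenset(members), GeneSetKind.similar_disease_targets)
        )
    for i in range(config.n_similar_noise):
        members = set(_sample(rng, set(ids) - set(shared), config.similar_noise_members + 5))
        similar.append(
            GeneSet(
                f"simnoise_{i:02d}", frozenset(members), GeneSetKind.similar_disease_targets
            )
        )

    kb = KnowledgeBase(
        proteins=proteins,
        interactions=interactions,
        pathway_maps=pathway_maps,
        metaminer_pathways=metaminer,
        linear_pathways=chains,
        disorder_annotations=annotations,
        similar_disease_candidates=similar,
    )
    kb.validate()

    truth = SyntheticTruth(
        planted_targets=frozenset(shared),
        module_membership={d: frozenset(m) for d, m in modules.items()},
        informative_features={
            "knowledge": True,
            "network": True,
            "metaminer": True,
            "similarity": True,
        },
    )
    assert truth.planted_targets == define_positive_controls(kb)
    return kb, truth
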