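"""Domain model of the curated knowledge base and its on-disk formats.

The knowledge base bundles everything the prioritization pipeline consumes:
a protein universe, a direct physical protein-protein interaction network
(with per-edge effect and mechanism annotations), pathway-map gene sets,
consortium-curated pathway gene sets, linear signaling chains running from a
ligand-receptor event to a transcription factor, per-disorder biomarker and
drug-target annotations, and candidate gene sets for "similar" diseases.

File formats are deliberately plain: a 4-column TSV edge list, GMT for every
gene-set collection, a 2-column TSV for linear chains and a YAML manifest for
the disorder annotations. ``write_kb``/``read_kb`` round-trip a whole
knowledge base through a directory of these files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "Effect",
    "Mechanism",
    "TargetStatus",
    "GeneSetKind",
    "Protein",
    "Interaction",
    "GeneSet",
    "LinearPathway",
    "DisorderAnnotation",
    "KnowledgeBase",
    "KBFormatError",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_linear_pathways",
    "write_linear_pathways",
    "build_graph",
    "write_kb",
    "read_kb",
]


class KBFormatError(ValueError):
    """A knowledge-base file violates its format contract."""


class Effect(str, Enum):
    activation = "activation"
    inhibition = "inhibition"
    unspecified = "unspecified"


class Mechanism(str, Enum):
    """Direct physical interaction mechanisms admitted into the network.

    Indirect mechanisms (e.g. influence on expression) are excluded by
    construction: they are not members of this enum, so loaders reject them.
    """

    binding = "binding"
    competition = "competition"
    transformation = "transformation"
    cleavage = "cleavage"
    catalysis = "catalysis"
    transport = "transport"
    receptor_binding = "receptor_binding"
    transport_catalysis = "transport_catalysis"
    phosphorylation = "phosphorylation"
    dephosphorylation = "dephosphorylation"
    ubiquitination = "ubiquitination"
    deubiquitination = "deubiquitination"
    sumoylation = "sumoylation"
    desumoylation = "desumoylation"
    neddylation = "neddylation"
    deneddylation = "deneddylation"
    covalent_modification = "covalent_modification"


class TargetStatus(str, Enum):
    validated = "validated"
    candidate = "candidate"
    exploratory = "exploratory"


class GeneSetKind(str, Enum):
    pathway_map = "pathway_map"
    disease_pathway_map = "disease_pathway_map"
    metaminer_pathway = "metaminer_pathway"
    biomarker_set = "biomarker_set"
    target_set = "target_set"
    annotation_term = "annotation_term"
    similar_disease_targets = "similar_disease_targets"


@dataclass(frozen=True)
class Protein:
    id: int
    symbol: str

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError(f"protein {self.id} has an empty symbol")


@dataclass(frozen=True)
class Interaction:
    source: int
    target: int
    effect: Effect
    mechanism: Mechanism

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-interaction on protein {self.source}")

    @property
    def key(self) -> tuple[int, int]:
        """Undirected edge key (sorted endpoint pair)."""
        a, b = self.source, self.target
        return (a, b) if a <= b else (b, a)


@dataclass
class GeneSet:
    name: str
    members: frozenset[int]
    kind: GeneSetKind
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set with empty name")
        self.members = frozenset(int(m) for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class LinearPathway:
    """Ordered signaling chain: chain[0] is the ligand/receptor start,
    chain[-1] the transcription-factor end."""

    name: str
    chain: tuple[int, ...]

    def __post_init__(self) -> None:
        self.chain = tuple(int(p) for p in self.chain)
        if len(self.chain) < 2:
            raise ValueError(f"linear pathway {self.name!r} shorter than 2")

    def __contains__(self, protein_id: int) -> bool:
        return protein_id in self.chain


@dataclass
class DisorderAnnotation:
    disorder: str
    biomarkers: GeneSet
    targets: GeneSet
    target_status: dict[int, TargetStatus]

    def __post_init__(self) -> None:
        # targets without a development status are dropped, not kept unlabeled
        missing = self.targets.members - set(self.target_status)
        if missing:
            self.targets = GeneSet(
                self.targets.name,
                self.targets.members - missing,
                self.targets.kind,
                self.targets.description,
            )


@dataclass
class KnowledgeBase:
    proteins: dict[int, Protein]
    interactions: list[Interaction]
    pathway_maps: list[GeneSet] = field(default_factory=list)
    metaminer_pathways: list[GeneSet] = field(default_factory=list)
    linear_pathways: list[LinearPathway] = field(default_factory=list)
    disorder_annotations: dict[str, DisorderAnnotation] = field(default_factory=dict)
    similar_disease_candidates: list[GeneSet] = field(default_factory=list)

    @property
    def universe(self) -> list[int]:
        """Sorted protein ids; the row index of every score vector."""
        return sorted(self.proteins)

    @property
    def disorders(self) -> list[str]:
        return sorted(self.disorder_annotations)

    def validate(self) -> None:
        """Check that every cross-reference resolves in the protein table."""
        ids = set(self.proteins)
        for it in self.interactions:
            if it.source not in ids or it.target not in ids:
                raise KBFormatError(
                    f"interaction {it.source}-{it.target} references unknown protein"
                )
        collections: list[Iterable[GeneSet]] = [
            self.pathway_maps,
            self.metaminer_pathways,
            self.similar_disease_candidates,
        ]
        for coll in collections:
            for gs in coll:
                if not gs.members <= ids:
                    raise KBFormatError(f"gene set {gs.name!r} has unknown members")
        for lp in self.linear_pathways:
            if not set(lp.chain) <= ids:
                raise KBFormatError(f"linear pathway {lp.name!r} has unknown members")
        for ann in self.disorder_annotations.values():
            for gs in (ann.biomarkers, ann.targets):
                if not gs.members <= ids:
                    raise KBFormatError(
                        f"disorder {ann.disorder!r} set {gs.name!r} has unknown members"
                    )


# ---------------------------------------------------------------------------
# Edge-list TSV
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["source_id", "target_id", "effect", "mechanism"]


def read_edge_list(path: str | Path) -> tuple[list[Interaction], int]:
    """Read a 4-column TSV edge list into undirected interactions.

    Duplicate undirected edges collapse to the first record seen; self-loops
    are rejected and counted. Returns ``(interactions, n_self_loops)``.
    """
    path = Path(path)
    interactions: dict[tuple[int, int], Interaction] = {}
    n_self = 0
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_HEADER:
            raise KBFormatError(f"{path}: bad edge-list header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise KBFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                s, t = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise KBFormatError(f"{path}:{lineno}: non-integer id") from exc
            try:
                eff = Effect(fields[2])
            except ValueError as exc:
                raise KBFormatError(
                    f"{path}:{lineno}: unknown effect {fields[2]!r}"
                ) from exc
            try:
                mech = Mechanism(fields[3])
            except ValueError as exc:
                raise KBFormatError(
                    f"{path}:{lineno}: unknown mechanism {fields[3]!r}"
                ) from exc
            if s == t:
                n_self += 1
                continue
            it = Interaction(s, t, eff, mech)
            interactions.setdefault(it.key, it)
    if n_self:
        warnings.warn(f"{path}: rejected {n_self} self-loop record(s)", stacklevel=2)
    return list(interactions.values()), n_self


def write_edge_list(path: str | Path, interactions: Sequence[Interaction]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for it in sorted(interactions, key=lambda i: i.key):
            a, b = it.key
            fh.write(f"{a}\t{b}\t{it.effect.value}\t{it.mechanism.value}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(
    path: str | Path,
    kind: GeneSetKind,
    universe: set[int] | None = None,
) -> list[GeneSet]:
    """Read a GMT file (name, description, member ids per line).

    Member ids absent from ``universe`` (when given) are dropped with a
    warning; lines whose member list is empty are skipped with a warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    n_dropped = 0
    n_empty = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise KBFormatError(f"{path}:{lineno}: malformed GMT line")
            name, desc = fields[0], fields[1]
            try:
                members = {int(f) for f in fields[2:] if f}
            except ValueError as exc:
                raise KBFormatError(f"{path}:{lineno}: non-integer member id") from exc
            if universe is not None:
                resolved = members & universe
                n_dropped += len(members) - len(resolved)
                members = resolved
            if not members:
                n_empty += 1
                continue
            sets.append(GeneSet(name, frozenset(members), kind, desc))
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} unresolvable member id(s)", stacklevel=2)
    if n_empty:
        warnings.warn(f"{path}: skipped {n_empty} empty gene set(s)", stacklevel=2)
    return sets


def write_gmt(path: str | Path, sets: Sequence[GeneSet]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gs in sets:
            members = "\t".join(str(m) for m in sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# Linear pathways TSV
# ---------------------------------------------------------------------------


def read_linear_pathways(path: str | Path) -> list[LinearPathway]:
    path = Path(path)
    chains: list[LinearPathway] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise KBFormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                chain = tuple(int(p) for p in fields[1].split(">"))
            except ValueError as exc:
                raise KBFormatError(f"{path}:{lineno}: malformed chain") from exc
            chains.append(LinearPathway(fields[0], chain))
    return chains


def write_linear_pathways(path: str | Path, chains: Sequence[LinearPathway]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for lp in chains:
            fh.write(f"{lp.name}\t{'>'.join(str(p) for p in lp.chain)}\n")


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_graph(kb: KnowledgeBase) -> nx.Graph:
    """Undirected simple graph over the full protein universe.

    Isolated proteins are kept as degree-0 nodes: prioritization is
    genome-wide and such proteins can still receive knowledge-based and
    similarity scores. Edge metadata (effect, mechanism) is retained but all
    topological scoring is orientation-free.
    """
    g = nx.Graph()
    g.add_nodes_from(kb.universe)
    for it in kb.interactions:
        a, b = it.key
        g.add_edge(a, b, effect=it.effect.value, mechanism=it.mechanism.value)
    return g


# ---------------------------------------------------------------------------
# Whole-KB directory round trip
# ---------------------------------------------------------------------------


def write_kb(kb: KnowledgeBase, outdir: str | Path) -> None:
    """Serialize a knowledge base to a directory of plain-text files.

    Output is fully sorted, so identical knowledge bases serialize to
    byte-identical directories.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "proteins.tsv").open("w") as fh:
        fh.write("id\tsymbol\n")
        for pid in sorted(kb.proteins):
            fh.write(f"{pid}\t{kb.proteins[pid].symbol}\n")
    write_edge_list(outdir / "interactions.tsv", kb.interactions)
    write_gmt(outdir / "pathway_maps.gmt", kb.pathway_maps)
    write_gmt(outdir / "metaminer_pathways.gmt", kb.metaminer_pathways)
    write_linear_pathways(outdir / "linear_pathways.tsv", kb.linear_pathways)
    write_gmt(outdir / "similar_diseases.gmt", kb.similar_disease_candidates)
    biom = [kb.disorder_annotations[d].biomarkers for d in kb.disorders]
    targ = [kb.disorder_annotations[d].targets for d in kb.disorders]
    write_gmt(outdir / "biomarkers.gmt", biom)
    write_gmt(outdir / "targets.gmt", targ)
    manifest = {
        "disorders": {
            d: {
                "biomarkers": kb.disorder_annotations[d].biomarkers.name,
                "targets": kb.disorder_annotations[d].targets.name,
                "target_status": {
                    str(pid): status.value
                    for pid, status in sorted(
                        kb.disorder_annotations[d].target_status.items()
                    )
                },
            }
            for d in kb.disorders
        }
    }
    with (outdir / "disorders.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_kb(indir: str | Path) -> KnowledgeBase:
    indir = Path(indir)
    if not indir.is_dir():
        raise KBFormatError(f"knowledge-base directory {indir} does not exist")
    proteins: dict[int, Protein] = {}
    with (indir / "proteins.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "symbol"]:
            raise KBFormatError(f"{indir}/proteins.tsv: bad header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid_s, symbol = line.split("\t")
            pid = int(pid_s)
            proteins[pid] = Protein(pid, symbol)
    ids = set(proteins)
    interactions, _ = read_edge_list(indir / "interactions.tsv")
    pathway_maps = read_gmt(indir / "pathway_maps.gmt", GeneSetKind.pathway_map, ids)
    metaminer = read_gmt(
        indir / "metaminer_pathways.gmt", GeneSetKind.metaminer_pathway, ids
    )
    chains = read_linear_pathways(indir / "linear_pathways.tsv")
    similar = read_gmt(
        indir / "similar_diseases.gmt", GeneSetKind.similar_disease_targets, ids
    )
    biom = {
        gs.name: gs for gs in read_gmt(indir / "biomarkers.gmt", GeneSetKind.biomarker_set, ids)
    }
    targ = {
        gs.name: gs for gs in read_gmt(indir / "targets.gmt", GeneSetKind.target_set, ids)
    }
    with (indir / "disorders.yaml").open() as fh:
        manifest = yaml.safe_load(fh)
    annotations: dict[str, DisorderAnnotation] = {}
    for disorder, entry in manifest["disorders"].items():
        annotations[disorder] = DisorderAnnotation(
            disorder=disorder,
            biomarkers=biom[entry["biomarkers"]],
            targets=targ[entry["targets"]],
            target_status={
                int(pid): TargetStatus(status)
                for pid, status in entry["target_status"].items()
            },
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
    return kb
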