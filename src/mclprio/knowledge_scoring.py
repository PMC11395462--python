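"""The five knowledge-based per-protein scores.

For a given disorder, prior knowledge contributes five evidence channels:

1. **biomarker indicator** — 1 if the protein is an annotated biomarker;
2. **interaction inference** — -ln of the hypergeometric over-representation
   of disorder biomarkers among the protein's direct network neighbors;
3. **pathway enrichment** — each pathway map gets -ln of its biomarker
   enrichment p; a protein sums the scores of the pathways containing it;
4. **consortium pathway count** — number of consortium-curated pathways the
   protein appears on (disorder-independent);
5. **linear-pathway ratio** — fraction of ligand-to-transcription-factor
   signaling chains containing the protein that also contain a biomarker.

"log-transformed p-value" is read as the natural log throughout; the base
only rescales features and the downstream classifier standardizes columns.
p-values are clamped below at 1e-300 before logging and all -ln(p) scores
are clamped at 0. The hypergeometric universe is the full protein universe
of the knowledge base.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .enrichment_stats import NEGLOG_P_CLAMP, hypergeom_tail
from .kb_model import KnowledgeBase, build_graph

__all__ = [
    "biomarker_score",
    "interaction_inference",
    "pathway_enrichment_score",
    "metaminer_count",
    "linear_pathway_score",
    "knowledge_score_table",
]


def _annotation(kb: KnowledgeBase, disorder: str):
    try:
        return kb.disorder_annotations[disorder]
    except KeyError:
        raise KeyError(f"unknown disorder {disorder!r}") from None


def _neglog(p: np.ndarray | float) -> np.ndarray | float:
    return np.maximum(0.0, -np.log(np.clip(p, NEGLOG_P_CLAMP, 1.0)))


def biomarker_score(kb: KnowledgeBase, disorder: str) -> pd.Series:
    """Binary membership of the disorder's biomarker set."""
    ann = _annotation(kb, disorder)
    universe = kb.universe
    values = np.fromiter(
        (1.0 if pid in ann.biomarkers.members else 0.0 for pid in universe),
        dtype=float,
        count=len(universe),
    )
    return pd.Series(values, index=universe)


def interaction_inference(
    kb: KnowledgeBase, disorder: str, graph=None
) -> pd.Series:
    """-ln p of biomarker over-representation among each protein's neighbors.

    For protein i with degree d > 0 and b biomarkers among its neighbors,
    p = P(X >= b) for X ~ Hypergeometric(N=universe, K=|biomarkers|, n=d).
    Degree-0 proteins score 0.
    """
    ann = _annotation(kb, disorder)
    if graph is None:
        graph = build_graph(kb)
    universe = kb.universe
    biomarkers = ann.biomarkers.members
    n_univ = len(universe)
    n_biom = len(biomarkers)
    deg = np.zeros(len(universe), dtype=int)
    hits = np.zeros(len(universe), dtype=int)
    for i, pid in enumerate(universe):
        neigh = graph[pid]
        deg[i] = len(neigh)
        hits[i] = sum(1 for nb in neigh if nb in biomarkers)
    # vectorized upper tail P(X >= hits); sf(k-1) gives P(X >= k)
    p = np.ones(len(universe))
    nz = deg > 0
    p[nz] = hypergeom.sf(hits[nz] - 1, n_univ, n_biom, deg[nz])
    scores = np.where(nz, _neglog(p), 0.0)
    return pd.Series(scores, index=universe)


def pathway_enrichment_score(kb: KnowledgeBase, disorder: str) -> pd.Series:
    """Sum over containing pathway maps of each map's -ln enrichment p.

    A pathway map P holding r of the disorder's biomarkers scores
    ``s_P = -ln P(X >= r | N, |biomarkers|, |P|)``; a protein adds up s_P
    across the maps it appears on.
    """
    ann = _annotation(kb, disorder)
    universe = kb.universe
    index = {pid: i for i, pid in enumerate(universe)}
    biomarkers = ann.biomarkers.members
    n_univ = len(universe)
    scores = np.zeros(len(universe))
    for gs in kb.pathway_maps:
        r = len(gs.members & biomarkers)
        s = _neglog(hypergeom_tail(r, len(gs.members), len(biomarkers), n_univ))
        if s <= 0.0:
            continue
        for pid in gs.members:
            scores[index[pid]] += s
    return pd.Series(scores, index=universe)


def metaminer_count(kb: KnowledgeBase) -> pd.Series:
    """Number of consortium-curated pathways each protein appears on."""
    universe = kb.universe
    index = {pid: i for i, pid in enumerate(universe)}
    counts = np.zeros(len(universe))
    for gs in kb.metaminer_pathways:
        for pid in gs.members:
            counts[index[pid]] += 1
    return pd.Series(counts, index=universe)


def linear_pathway_score(kb: KnowledgeBase, disorder: str) -> pd.Series:
    """Fraction of a protein's signaling chains that carry a biomarker.

    ratio = (#chains containing the protein and >= 1 biomarker)
          / (#chains containing the protein); proteins on no chain score 0
    (absence from every chain carries no evidence).
    """
    ann = _annotation(kb, disorder)
    biomarkers = ann.biomarkers.members
    universe = kb.universe
    index = {pid: i for i, pid in enumerate(universe)}
    on_chain = np.zeros(len(universe))
    with_biom = np.zeros(len(universe))
    for lp in kb.linear_pathways:
        chain_set = set(lp.chain)
        has_biom = bool(chain_set & biomarkers)
        for pid in chain_set:
            on_chain[index[pid]] += 1
            if has_biom:
                with_biom[index[pid]] += 1
    ratio = np.divide(
        with_biom, on_chain, out=np.zeros_like(with_biom), where=on_chain > 0
    )
    return pd.Series(ratio, index=universe)


def knowledge_score_table(kb: KnowledgeBase, graph=None) -> pd.DataFrame:
    """All knowledge scores: 4 per-disorder columns plus the global count.

    Columns are named ``<disorder>.<method>`` (biomarker, interaction,
    pathway, linear) plus ``metaminer.count``.
    """
    if graph is None:
        graph = build_graph(kb)
    columns: dict[str, pd.Series] = {}
    for disorder in kb.disorders:
        columns[f"{disorder}.biomarker"] = biomarker_score(kb, disorder)
        columns[f"{disorder}.interaction"] = interaction_inference(kb, disorder, graph)
        columns[f"{disorder}.pathway"] = pathway_enrichment_score(kb, disorder)
        columns[f"{disorder}.linear"] = linear_pathway_score(kb, disorder)
    columns["metaminer.count"] = metaminer_count(kb)
    return pd.DataFrame(columns)
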