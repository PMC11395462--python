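"""Disease-similarity features for drug repositioning.

Diseases sharing aspects of molecular pathology are found by testing the
overlap between their gene sets with a hypergeometric test: similarity is
-log10 of the upper-tail probability of the observed overlap. The k most
similar candidate diseases that share at least ``min_shared`` targets with
the gold-standard training set (the pooled >= 2-indication positive
controls) are selected, and each contributes one binary feature column
marking its known targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import NEGLOG_P_CLAMP, hypergeom_tail
from .kb_model import GeneSet

__all__ = [
    "SimilarityRecord",
    "disease_similarity",
    "select_similar_diseases",
    "similarity_features",
]


@dataclass(frozen=True)
class SimilarityRecord:
    disease: str
    overlap: int
    similarity: float  # -log10 hypergeometric tail p of the overlap
    selected: bool


def disease_similarity(
    set_a: Iterable[int], set_b: Iterable[int], universe_size: int
) -> float:
    """-log10 P(overlap >= |A & B|) under the hypergeometric null.

    Empty input sets have no measurable overlap and score 0 (with a
    warning); the result is clamped at 0.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        warnings.warn("empty gene set in similarity test: similarity = 0", stacklevel=2)
        return 0.0
    p = hypergeom_tail(len(a & b), len(a), len(b), universe_size)
    return float(max(0.0, -np.log10(max(p, NEGLOG_P_CLAMP))))


def select_similar_diseases(
    candidates: Sequence[GeneSet],
    reference_target_set: Iterable[int],
    universe_size: int,
    k: int = 15,
    min_shared: int = 3,
) -> list[SimilarityRecord]:
    """Rank candidate diseases by similarity to the reference target set.

    Candidates sharing fewer than ``min_shared`` targets are ineligible
    regardless of similarity. The top ``k`` eligible candidates are flagged
    selected; ties in p break lexicographically by disease name. All
    candidates are returned (selected and not), ranked.
    """
    reference = set(reference_target_set)
    records = []
    for gs in candidates:
        overlap = len(gs.members & reference)
        sim = disease_similarity(gs.members, reference, universe_size)
        records.append((gs.name, overlap, sim))
    records.sort(key=lambda rec: (-rec[2], rec[0]))
    eligible = [rec for rec in records if rec[1] >= min_shared]
    if len(eligible) < k:
        warnings.warn(
            f"only {len(eligible)} candidate disease(s) share >= {min_shared} "
            f"targets; selecting all of them",
            stacklevel=2,
        )
    selected_names = {rec[0] for rec in eligible[:k]}
    return [
        SimilarityRecord(name, overlap, sim, name in selected_names)
        for name, overlap, sim in records
    ]


def similarity_features(
    selected: Sequence[GeneSet], universe: Sequence[int]
) -> pd.DataFrame:
    """One binary column per selected disease: 1 if the protein is one of
    its known targets, else 0."""
    universe = list(universe)
    data = {}
    for gs in selected:
        members = gs.members
        data[f"similar.{gs.name}"] = np.fromiter(
            (1.0 if pid in members else 0.0 for pid in universe),
            dtype=float,
            count=len(universe),
        )
    return pd.DataFrame(data, index=universe)
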