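"""Evaluation of a prioritization: ROC/AUC, fold enrichment, rank summaries
and top-K subnetwork extraction.

Scores are rank-style: low = best. AUC is computed with the tie-corrected
rank-sum formulation, which equals the trapezoidal area under the ROC curve.
Evaluation uses cross-validated (held-out) genome-wide scores where
available, so recovery statistics are not inflated by training leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .kb_model import Interaction, KnowledgeBase

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "fold_enrichment",
    "rank_summary",
    "extract_top_subnetwork",
    "evaluate",
]


@dataclass
class EvaluationReport:
    auc: float
    roc_points: pd.DataFrame  # columns fpr, tpr
    fold_enrichment: float
    top_k: int
    recovered_positives: int
    rank_mean: float
    rank_median: float
    rank_min: float
    rank_max: float


def roc_auc(
    final_scores: pd.Series, positives: Iterable[int]
) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC for recovering the positives (low score = best).

    The ROC sweeps all score thresholds; AUC is the tie-corrected rank-sum
    statistic, identical to the trapezoidal area under the curve.
    """
    positives = set(positives)
    if not positives:
        raise ValueError("no positives to evaluate")
    labels = np.fromiter(
        (1 if pid in positives else 0 for pid in final_scores.index),
        dtype=int,
        count=len(final_scores),
    )
    if labels.sum() == len(labels):
        raise ValueError("every protein is a positive; ROC undefined")
    scores = -final_scores.to_numpy(dtype=float)  # high = target-like
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    n_pos, n_neg = int(labels.sum()), int(len(labels) - labels.sum())
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), float(auc)


def fold_enrichment(
    final_scores: pd.Series | None,
    positives: Iterable[int] | int,
    K: int,
    universe_size: int | None = None,
    hits: int | None = None,
) -> float:
    """Observed/expected enrichment of positives among the top K.

    ``(hits/K) / (|positives|/N)``: the factor by which known targets are
    over-represented in the top-K list relative to the genome-wide baseline.
    Either pass scores + positive ids, or the raw counts
    (``hits``, ``positives`` as a count, ``universe_size``). Depends only on
    ranks, so any monotone rescaling of scores leaves it unchanged.
    """
    if hits is not None:
        n_pos = int(positives)  # type: ignore[arg-type]
        if universe_size is None:
            raise ValueError("universe_size required with raw counts")
        n = universe_size
    else:
        assert final_scores is not None
        positives = set(positives)  # type: ignore[arg-type]
        n = len(final_scores)
        if K > n:
            raise ValueError("K exceeds the universe size")
        top = final_scores.nsmallest(K).index
        hits = sum(1 for pid in top if pid in positives)
        n_pos = len(positives)
    if n_pos == 0:
        raise ValueError("no positives")
    return (hits / K) / (n_pos / n)


def rank_summary(final_scores: pd.Series, K: int) -> dict[str, float]:
    """Mean/median/min/max of the K best final scores."""
    if K < 1:
        raise ValueError("K must be >= 1")
    top = final_scores.nsmallest(K).to_numpy(dtype=float)
    return {
        "mean": float(np.mean(top)),
        "median": float(np.median(top)),
        "min": float(np.min(top)),
        "max": float(np.max(top)),
    }


def extract_top_subnetwork(
    kb: KnowledgeBase, final_scores: pd.Series, K: int
) -> list[Interaction]:
    """Direct interactions among the top-K proteins, effect labels kept."""
    top = set(final_scores.nsmallest(K).index)
    return [it for it in kb.interactions if it.source in top and it.target in top]


def evaluate(
    final_scores: pd.Series, positives: Iterable[int], K: int = 250
) -> EvaluationReport:
    positives = set(positives)
    roc, auc = roc_auc(final_scores, positives)
    top = final_scores.nsmallest(K)
    recovered = sum(1 for pid in top.index if pid in positives)
    summary = rank_summary(final_scores, K)
    return EvaluationReport(
        auc=auc,
        roc_points=roc,
        fold_enrichment=fold_enrichment(final_scores, positives, K),
        top_k=K,
        recovered_positives=recovered,
        rank_mean=summary["mean"],
        rank_median=summary["median"],
        rank_min=summary["min"],
        rank_max=summary["max"],
    )
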