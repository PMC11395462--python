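"""Evidence integration: PLS classification inside balanced nested CV.

The evidence channels (per-disorder knowledge scores, the global consortium
pathway count, four network scores seeded at the pooled disorder biomarkers,
and binary similar-disease target features) are assembled into a proteins x
features matrix. A partial-least-squares classifier is trained on the
positive controls (targets with >= 2 indications) against a 10x oversampled
random negative class, inside a balanced (stratified) nested 5x5
cross-validation whose inner loop performs recursive feature elimination.
Each outer-fold model scores the whole proteome; scores are converted to
genome-wide ranks within each repeat and ranks are averaged over repeats to
produce the final prioritization (low rank = best).

Methodological choices the procedure leaves open and how they are fixed
here: prediction error is 1 - AUC on the inner validation folds
(threshold-free, matching the final ROC evaluation; misclassification rate
available via ``CVConfig.error_metric``); feature importance for RFE is the
mean absolute PLS regression weight on standardized features; the
genome-wide score of a repeat is the mean of its five outer-fold models;
rank ties receive average ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .disease_similarity import select_similar_diseases, similarity_features
from .kb_model import KnowledgeBase, build_graph
from .knowledge_scoring import knowledge_score_table
from .network_scoring import (
    NeighborhoodParams,
    PropagationParams,
    RWRParams,
    interconnectivity_score,
    network_propagation,
    neighborhood_score,
    random_walk_restart,
)
from .synthetic_kb import define_positive_controls

__all__ = [
    "FeatureMatrix",
    "CVConfig",
    "PrioritizationResult",
    "build_feature_matrix",
    "compute_feature_matrix",
    "sample_negatives",
    "rfe_inner_loop",
    "nested_cv_prioritize",
]


@dataclass
class FeatureMatrix:
    """Proteins x evidence-feature scores with per-column provenance.

    ``raw`` keeps the unstandardized values; ``X`` is the z-scored array
    actually used for modeling (constant columns are dropped with a
    warning). Column-name prefixes carry provenance: ``<disorder>.``,
    ``metaminer.``, ``network.``, ``similar.``.
    """

    raw: pd.DataFrame
    X: np.ndarray = field(init=False, repr=False)
    columns: list[str] = field(init=False)
    dropped: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.raw.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if not np.isfinite(self.raw.to_numpy()).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.raw.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        std = self.raw.std(axis=0, ddof=0)
        self.dropped = list(self.raw.columns[std == 0.0])
        if self.dropped:
            warnings.warn(
                f"dropping {len(self.dropped)} constant feature column(s): "
                f"{self.dropped[:5]}",
                stacklevel=2,
            )
        kept = self.raw.drop(columns=self.dropped)
        self.columns = list(kept.columns)
        values = kept.to_numpy(dtype=float)
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        self.X = (values - mu) / sd

    @property
    def index(self) -> pd.Index:
        return self.raw.index

    def __len__(self) -> int:
        return len(self.raw)


def build_feature_matrix(frames: Sequence[pd.DataFrame]) -> FeatureMatrix:
    """Assemble feature blocks computed on the same protein universe."""
    if not frames:
        raise ValueError("no feature blocks given")
    index = frames[0].index
    for i, frame in enumerate(frames[1:], start=1):
        if not frame.index.equals(index):
            raise ValueError(f"feature block {i} is on a different protein universe")
    return FeatureMatrix(pd.concat(frames, axis=1))


def compute_feature_matrix(
    kb: KnowledgeBase,
    propagation: PropagationParams = PropagationParams(),
    rwr: RWRParams = RWRParams(),
    neighborhood: NeighborhoodParams = NeighborhoodParams(),
    n_similar: int = 15,
    min_shared: int = 3,
) -> FeatureMatrix:
    """Run every scoring module on a knowledge base and assemble the matrix.

    Network scores are seeded with the pooled biomarkers of all disorders
    (the disorders are treated as one prioritization task); similar-disease
    features come from the top candidates against the pooled >= 2-indication
    positive-control set.
    """
    graph = build_graph(kb)
    knowledge = knowledge_score_table(kb, graph)
    pooled_biomarkers = sorted(
        set().union(
            *(ann.biomarkers.members for ann in kb.disorder_annotations.values())
        )
    )
    network = pd.DataFrame(
        {
            "network.propagation": network_propagation(graph, pooled_biomarkers, propagation),
            "network.rwr": random_walk_restart(graph, pooled_biomarkers, rwr),
            "network.icn": interconnectivity_score(graph, pooled_biomarkers),
            "network.neighborhood": neighborhood_score(
                graph, pooled_biomarkers, neighborhood
            ),
        }
    )
    positives = define_positive_controls(kb)
    records = select_similar_diseases(
        kb.similar_disease_candidates,
        positives,
        len(kb.universe),
        k=n_similar,
        min_shared=min_shared,
    )
    selected_names = {rec.disease for rec in records if rec.selected}
    selected_sets = [
        gs for gs in kb.similar_disease_candidates if gs.name in selected_names
    ]
    similar = similarity_features(selected_sets, kb.universe)
    return build_feature_matrix([knowledge, network, similar])


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 10
    neg_pos_ratio: int = 10
    pls_components: int = 2
    rfe_step: int = 1
    rng_seed: int = 0
    error_metric: str = "one_minus_auc"  # or "misclassification"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be >= 1")
        if self.pls_components < 1:
            raise ValueError("pls_components must be >= 1")
        if self.error_metric not in ("one_minus_auc", "misclassification"):
            raise ValueError(f"unknown error metric {self.error_metric!r}")


@dataclass
class PrioritizationResult:
    """Genome-wide prioritization with cross-validation diagnostics.

    ``final_score`` is the mean over repeats of each protein's genome-wide
    rank under the all-model average score (low = best); ``heldout_score``
    averages only models that never saw the protein during training and is
    what performance evaluation uses. ``feature_selection_counts`` counts,
    per feature, the outer-fold RFE runs (repeats x outer_folds in total)
    that retained it. ``error_curve`` maps feature count to the mean inner
    prediction error across all RFE runs.
    """

    final_score: pd.Series
    heldout_score: pd.Series
    per_repeat_ranks: pd.DataFrame
    feature_selection_counts: pd.Series
    error_curve: pd.Series
    config: CVConfig


def sample_negatives(
    universe: Sequence[int],
    positives: Iterable[int],
    ratio: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform sample (without replacement) of non-positive proteins,
    ``ratio`` times the positive count, disjoint from the positives."""
    positives = set(positives)
    pool = np.asarray([pid for pid in universe if pid not in positives])
    k = ratio * len(positives)
    if len(pool) < k:
        raise ValueError(
            f"cannot sample {k} negatives from {len(pool)} non-positive proteins"
        )
    return rng.choice(pool, size=k, replace=False)


def _auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected rank-sum AUC of continuous scores (high = positive)."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    model = PLSRegression(
        n_components=min(n_components, X.shape[1], X.shape[0] - 1), scale=False
    )
    model.fit(X, y.astype(float).reshape(-1, 1))
    return model


def _predict(model: PLSRegression, X: np.ndarray) -> np.ndarray:
    return model.predict(X).ravel()


def _fold_error(scores: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "one_minus_auc":
        return 1.0 - _auc_from_scores(scores, y)
    return float(np.mean((scores >= 0.5).astype(int) != y))


def rfe_inner_loop(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Recursive feature elimination with inner-CV error tracking.

    At each step the inner stratified CV is run on the active feature set;
    the validation prediction error and the mean absolute PLS weight per
    feature are recorded, then the ``rfe_step`` least informative feature(s)
    are dropped. Elimination stops once fewer than ``pls_components``
    features would remain. Returns the active-set snapshot minimizing the
    inner error (ties -> fewer features) and the full error curve as
    ``(n_features, error)`` pairs in elimination order.
    """
    n_features = X.shape[1]
    active = np.arange(n_features)
    curve: list[tuple[int, float]] = []
    snapshots: list[np.ndarray] = []
    splitter_seed = int(rng.integers(0, 2**31 - 1))
    while True:
        skf = StratifiedKFold(
            n_splits=config.inner_folds, shuffle=True, random_state=splitter_seed
        )
        errors = []
        importance = np.zeros(active.size)
        for train_idx, val_idx in skf.split(X, y):
            model = _fit_pls(X[np.ix_(train_idx, active)], y[train_idx], config.pls_components)
            scores = _predict(model, X[np.ix_(val_idx, active)])
            errors.append(_fold_error(scores, y[val_idx], config.error_metric))
            importance += np.abs(model.coef_).ravel()
        curve.append((active.size, float(np.mean(errors))))
        snapshots.append(active.copy())
        if active.size - config.rfe_step < config.pls_components:
            break
        drop = np.argsort(importance)[: config.rfe_step]
        active = np.delete(active, drop)
    errs = np.array([e for _, e in curve])
    sizes = np.array([s for s, _ in curve])
    best_err = errs.min()
    # ties -> fewer features: among minimal-error steps take the smallest set
    candidates = np.flatnonzero(errs == best_err)
    best = candidates[np.argmin(sizes[candidates])]
    return snapshots[best], curve


def nested_cv_prioritize(
    features: FeatureMatrix,
    positives: Iterable[int],
    config: CVConfig = CVConfig(),
) -> PrioritizationResult:
    """Balanced nested cross-validation with genome-wide rank averaging.

    Per repeat: the positives are split into ``outer_folds`` stratification
    groups; for each outer fold, negatives are drawn fresh (``neg_pos_ratio``
    x the training positives), the inner RFE loop selects the feature set,
    a PLS model is fit on it and scores the whole proteome. The five
    fold-model scores are averaged and converted to genome-wide ranks
    (ties -> average rank); ranks are averaged across repeats. Selection
    counts accumulate per feature over the repeats x outer_folds RFE runs.
    """
    universe = list(features.index)
    index_of = {pid: i for i, pid in enumerate(universe)}
    positives = sorted(set(positives))
    missing = [pid for pid in positives if pid not in index_of]
    if missing:
        raise ValueError(f"positives not in the feature universe: {missing[:5]}")
    if len(positives) < config.outer_folds:
        raise ValueError("fewer positives than outer folds")
    X = features.X
    n = len(universe)
    rng = np.random.default_rng(config.rng_seed)

    rank_accum = np.zeros(n)
    heldout_rank_accum = np.zeros(n)
    per_repeat = {}
    counts = np.zeros(X.shape[1])
    curve_err: dict[int, list[float]] = {}

    pos_idx_all = np.array([index_of[pid] for pid in positives])
    pos_set = set(positives)
    non_pos_idx = np.array(
        [index_of[pid] for pid in universe if pid not in pos_set]
    )
    for rep in range(config.repeats):
        perm = rng.permutation(len(pos_idx_all))
        fold_of = np.arange(len(pos_idx_all)) % config.outer_folds
        fold_assign = np.empty(len(pos_idx_all), dtype=int)
        fold_assign[perm] = fold_of
        fold_scores = np.zeros((config.outer_folds, n))
        trained_on = np.zeros((config.outer_folds, n), dtype=bool)
        for fold in range(config.outer_folds):
            train_pos = pos_idx_all[fold_assign != fold]
            if train_pos.size == 0:
                raise ValueError("degenerate outer fold with no training positives")
            # fresh uniform negative draw per outer fold, 10x the training
            # positives, disjoint from all positives
            k_neg = config.neg_pos_ratio * train_pos.size
            if non_pos_idx.size < k_neg:
                raise ValueError(
                    f"cannot sample {k_neg} negatives from "
                    f"{non_pos_idx.size} non-positive proteins"
                )
            neg_idx = rng.choice(non_pos_idx, size=k_neg, replace=False)
            train_idx = np.concatenate([train_pos, neg_idx])
            y = np.concatenate(
                [np.ones(train_pos.size), np.zeros(neg_idx.size)]
            )
            selected, curve = rfe_inner_loop(X[train_idx], y, config, rng)
            counts[selected] += 1
            for size, err in curve:
                curve_err.setdefault(size, []).append(err)
            model = _fit_pls(X[np.ix_(train_idx, selected)], y, config.pls_components)
            fold_scores[fold] = _predict(model, X[:, selected])
            trained_on[fold, train_idx] = True
        mean_scores = fold_scores.mean(axis=0)
        ranks = rankdata(-mean_scores)  # low rank = best
        rank_accum += ranks
        per_repeat[f"repeat_{rep}"] = ranks
        # held-out score: average only the fold models that never trained on
        # the protein; proteins used by every fold model (rare) fall back to
        # the all-model mean
        free = ~trained_on
        free_count = free.sum(axis=0)
        with np.errstate(invalid="ignore"):
            ho = np.where(
                free_count > 0,
                (fold_scores * free).sum(axis=0) / np.maximum(free_count, 1),
                mean_scores,
            )
        heldout_rank_accum += rankdata(-ho)

    final = pd.Series(rank_accum / config.repeats, index=universe)
    heldout = pd.Series(heldout_rank_accum / config.repeats, index=universe)
    curve = pd.Series(
        {size: float(np.mean(errs)) for size, errs in sorted(curve_err.items())}
    )
    return PrioritizationResult(
        final_score=final,
        heldout_score=heldout,
        per_repeat_ranks=pd.DataFrame(per_repeat, index=universe),
        feature_selection_counts=pd.Series(counts, index=features.columns),
        error_curve=curve,
        config=config,
    )
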