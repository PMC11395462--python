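"""Feature-matrix assembly, negative sampling, RFE and nested CV mechanics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mclprio.evaluation import roc_auc
from mclprio.integration import (
    CVConfig,
    FeatureMatrix,
    build_feature_matrix,
    compute_feature_matrix,
    nested_cv_prioritize,
    rfe_inner_loop,
    sample_negatives,
)


def make_features(n=400, n_noise=9, seed=0, margin=6.0):
    """One feature that separates the positive class by a wide margin,
    plus pure-noise features."""
    rng = np.random.default_rng(seed)
    positives = sorted(rng.choice(np.arange(1, n + 1), size=n // 10, replace=False))
    signal = rng.normal(size=n)
    signal[np.asarray(positives) - 1] += margin
    noise = rng.normal(size=(n, n_noise))
    raw = pd.DataFrame(
        np.column_stack([signal, noise]),
        columns=["signal"] + [f"noise{i}" for i in range(n_noise)],
        index=range(1, n + 1),
    )
    return FeatureMatrix(raw), [int(p) for p in positives]


class TestFeatureMatrix:
    def test_expected_column_count_at_default_layout(self, small_kb):
        fm = compute_feature_matrix(small_kb, n_similar=8)
        d = len(small_kb.disorders)
        # 4 knowledge columns per disorder + global count + 4 network + 8 similarity
        assert fm.raw.shape[1] == 4 * d + 1 + 4 + 8
        assert list(fm.raw.index) == small_kb.universe

    def test_constant_column_dropped_with_warning(self):
        raw = pd.DataFrame(
            {"var": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]}, index=[1, 2, 3]
        )
        with pytest.warns(UserWarning, match="constant"):
            fm = FeatureMatrix(raw)
        assert fm.columns == ["var"]
        assert fm.dropped == ["const"]
        assert "const" in fm.raw.columns  # raw values retained

    def test_all_zero_raw_row_is_retained(self, small_kb):
        fm = compute_feature_matrix(small_kb, n_similar=8)
        # isolated evidence-free proteins are still rows of the matrix
        assert len(fm) == len(small_kb.universe)

    def test_universe_mismatch_raises(self):
        a = pd.DataFrame({"x": [1.0, 2.0]}, index=[1, 2])
        b = pd.DataFrame({"y": [1.0, 2.0]}, index=[1, 3])
        with pytest.raises(ValueError, match="different protein universe"):
            build_feature_matrix([a, b])

    def test_missing_values_rejected(self):
        raw = pd.DataFrame({"x": [1.0, np.nan]}, index=[1, 2])
        with pytest.raises(ValueError, match="missing"):
            FeatureMatrix(raw)

    def test_standardized_columns_have_zero_mean_unit_variance(self):
        fm, _ = make_features()
        assert np.allclose(fm.X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(fm.X.std(axis=0), 1.0, atol=1e-12)


class TestSampleNegatives:
    def test_size_and_disjointness(self):
        rng = np.random.default_rng(0)
        universe = list(range(1000))
        positives = set(range(50))
        negs = sample_negatives(universe, positives, 10, rng)
        assert len(negs) == 500
        assert len(set(negs)) == 500
        assert not set(negs) & positives

    def test_different_rng_states_give_different_samples(self):
        universe = list(range(1000))
        positives = set(range(50))
        draws = {
            tuple(sorted(sample_negatives(universe, positives, 10, np.random.default_rng(s))))
            for s in range(5)
        }
        assert len(draws) == 5

    def test_insufficient_pool_raises(self):
        with pytest.raises(ValueError, match="cannot sample"):
            sample_negatives(list(range(60)), set(range(50)), 10, np.random.default_rng(0))


class TestRFE:
    def test_separating_feature_is_retained(self):
        fm, positives = make_features()
        y = np.isin(np.array(fm.index), positives).astype(int)
        config = CVConfig(repeats=1, rng_seed=3)
        selected, curve = rfe_inner_loop(fm.X, y, config, np.random.default_rng(3))
        assert 0 in selected  # column 0 is the separating feature
        # curve runs from the full set down to the component floor, step 1
        sizes = [s for s, _ in curve]
        assert sizes[0] == fm.X.shape[1]
        assert sizes == list(range(fm.X.shape[1], config.pls_components - 1, -1))

    def test_error_curve_endpoint_is_full_feature_set(self):
        fm, positives = make_features(seed=5)
        y = np.isin(np.array(fm.index), positives).astype(int)
        _, curve = rfe_inner_loop(fm.X, y, CVConfig(), np.random.default_rng(0))
        assert curve[0][0] == fm.X.shape[1]
        assert len(curve) == fm.X.shape[1] - CVConfig().pls_components + 1


class TestNestedCV:
    def test_separable_labels_give_perfect_recovery(self):
        fm, positives = make_features()
        config = CVConfig(repeats=2, rng_seed=1)
        result = nested_cv_prioritize(fm, positives, config)
        _, auc = roc_auc(result.heldout_score, positives)
        assert auc == pytest.approx(1.0, abs=1e-3)
        top = result.final_score.nsmallest(len(positives)).index
        assert set(top) == set(positives)

    def test_final_scores_are_ranks_within_bounds(self):
        fm, positives = make_features(seed=2)
        result = nested_cv_prioritize(fm, positives, CVConfig(repeats=2, rng_seed=2))
        n = len(fm)
        assert result.final_score.between(1, n).all()
        for col in result.per_repeat_ranks:
            # each repeat's ranks are an average-tie permutation of 1..N
            assert result.per_repeat_ranks[col].sum() == pytest.approx(n * (n + 1) / 2)

    def test_selection_counts_bounded_by_repeats_times_folds(self):
        fm, positives = make_features(seed=3)
        config = CVConfig(repeats=2, rng_seed=0)
        result = nested_cv_prioritize(fm, positives, config)
        assert (result.feature_selection_counts >= 0).all()
        assert (
            result.feature_selection_counts <= config.repeats * config.outer_folds
        ).all()

    def test_identical_seed_reproduces_result_exactly(self):
        fm, positives = make_features(seed=4)
        config = CVConfig(repeats=2, rng_seed=9)
        r1 = nested_cv_prioritize(fm, positives, config)
        r2 = nested_cv_prioritize(fm, positives, config)
        assert r1.final_score.equals(r2.final_score)
        assert r1.feature_selection_counts.equals(r2.feature_selection_counts)
        assert r1.error_curve.equals(r2.error_curve)

    def test_positives_outside_universe_rejected(self):
        fm, _ = make_features()
        with pytest.raises(ValueError, match="not in the feature universe"):
            nested_cv_prioritize(fm, [10**9], CVConfig(repeats=1))

    def test_shuffled_labels_give_chance_level_recovery(self):
        """Leakage canary: with random pseudo-positives the held-out AUC must
        sit at chance, averaged over seeds."""
        fm, _ = make_features(n=500, seed=6)
        rng = np.random.default_rng(123)
        aucs = []
        for seed in range(4):
            pseudo = rng.choice(np.array(fm.index), size=40, replace=False)
            result = nested_cv_prioritize(
                fm, pseudo, CVConfig(repeats=1, rng_seed=seed)
            )
            _, auc = roc_auc(result.heldout_score, pseudo)
            aucs.append(auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.07
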