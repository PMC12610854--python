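import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguekin.evaluation import (
    DegenerateFoldError,
    ImbalanceStrategy,
    LeakageError,
    RFConfig,
    compute_class_weights,
    confusion_matrix,
    evaluate,
    loso_splits,
    macro_ovr_auc,
    macro_recall,
    oversample_indices,
    train_and_predict,
)
from fatiguekin.features import CLASSES, FEATURE_IDS
from helpers import brute_force_macro_ovr_auc, make_feature_table

RNG = np.random.default_rng(123)
FAST_RF = RFConfig(n_trees=60)


@pytest.fixture(scope="module")
def toy_table():
    labels = {
        f"S{i:02d}": ["Low"] * 4 + ["Medium"] * 3 + ["High"] * 5
        for i in range(1, 6)
    }
    return make_feature_table(labels, np.random.default_rng(0),
                              class_shift=4.0)


class TestLosoSplits:
    def test_one_fold_per_subject_partition(self, toy_table):
        splits = loso_splits(toy_table)
        assert len(splits) == 5
        test_union = np.concatenate([test for _, _, test in splits])
        assert sorted(test_union) == list(toy_table.index)
        for subject, train, test in splits:
            assert set(toy_table.loc[test, "subject_id"]) == {subject}
            assert subject not in set(toy_table.loc[train, "subject_id"])

    def test_two_subjects_two_folds(self):
        table = make_feature_table(
            {"A": ["Low", "High"], "B": ["Medium", "High"]}, RNG
        )
        assert len(loso_splits(table)) == 2

    def test_single_subject_rejected(self):
        table = make_feature_table({"A": ["Low", "High"]}, RNG)
        with pytest.raises(ValueError):
            loso_splits(table)


class TestClassWeights:
    def test_balanced_counts_unit_weights(self):
        w = compute_class_weights({"Low": 20, "Medium": 20, "High": 20})
        assert w == {"Low": 1.0, "Medium": 1.0, "High": 1.0}

    def test_formula_on_unbalanced_counts(self):
        w = compute_class_weights({"Low": 10, "Medium": 20, "High": 30})
        assert w["Low"] == pytest.approx(2.0)
        assert w["Medium"] == pytest.approx(1.0)
        assert w["High"] == pytest.approx(2 / 3)

    def test_zero_count_degenerate(self):
        with pytest.raises(DegenerateFoldError):
            compute_class_weights({"Low": 0, "Medium": 5, "High": 5})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(1, 500), st.integers(1, 500),
                     st.integers(1, 500)))
    def test_weighted_mass_equal_across_classes(self, counts):
        cdict = dict(zip(CLASSES, counts))
        w = compute_class_weights(cdict)
        masses = [cdict[c] * w[c] for c in CLASSES]
        np.testing.assert_allclose(masses, sum(counts) / 3)


class TestOversample:
    @staticmethod
    def _labels(n_low, n_med, n_high):
        return np.array(["Low"] * n_low + ["Medium"] * n_med
                        + ["High"] * n_high)

    def test_exact_balance_at_majority_count(self):
        labels = self._labels(5, 3, 2)
        idx = oversample_indices(labels, seed=42)
        resampled = labels[idx]
        assert all((resampled == c).sum() == 5 for c in CLASSES)

    def test_originals_all_retained(self):
        labels = self._labels(4, 2, 3)
        idx = oversample_indices(labels, seed=0)
        assert set(range(len(labels))) <= set(idx)

    def test_balanced_input_unchanged(self):
        labels = self._labels(3, 3, 3)
        assert np.array_equal(oversample_indices(labels, 42),
                              np.arange(9))

    def test_deterministic_given_seed(self):
        labels = self._labels(10, 4, 2)
        assert np.array_equal(oversample_indices(labels, 7),
                              oversample_indices(labels, 7))

    def test_missing_class_degenerate(self):
        with pytest.raises(DegenerateFoldError):
            oversample_indices(self._labels(5, 5, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(1, 40), st.integers(1, 40),
                     st.integers(1, 40)), st.integers(0, 2**31 - 1))
    def test_counts_equal_majority_property(self, counts, seed):
        labels = self._labels(*counts)
        resampled = labels[oversample_indices(labels, seed)]
        assert all((resampled == c).sum() == max(counts) for c in CLASSES)


class TestMacroOvrAuc:
    def test_perfect_separation_is_one(self):
        labels = np.array(["Low", "Low", "Medium", "Medium", "High", "High"])
        proba = np.zeros((6, 3))
        for i, lab in enumerate(labels):
            proba[i, CLASSES.index(lab)] = 1.0
        assert macro_ovr_auc(labels, proba) == 1.0

    def test_single_inversion_per_class_is_seven_eighths(self):
        # 2 positives x 4 negatives = 8 pairs per class; scores built so
        # exactly one pair is inverted -> AUC 7/8 per class and macro.
        labels = np.array(["Low", "Low", "Medium", "Medium", "High", "High"])
        col = {}
        for c, (i, j) in zip(CLASSES, [(0, 1), (2, 3), (4, 5)]):
            scores = np.full(6, 0.0)
            others = [k for k in range(6) if k not in (i, j)]
            scores[i] = 0.9
            scores[j] = 0.55
            scores[others] = [0.6, 0.3, 0.2, 0.1]   # 0.6 beats 0.55: 1 inversion
            col[c] = scores
        proba = np.column_stack([col[c] for c in CLASSES])
        assert macro_ovr_auc(labels, proba) == pytest.approx(7 / 8)
        assert brute_force_macro_ovr_auc(labels, proba) == pytest.approx(7 / 8)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        aucs = []
        for _ in range(1000):
            labels = rng.choice(CLASSES, size=30)
            while len(np.unique(labels)) < 2:
                labels = rng.choice(CLASSES, size=30)
            proba = rng.random((30, 3))
            aucs.append(macro_ovr_auc(labels, proba))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(6, 31)
            labels = rng.choice(CLASSES, size=n)
            if len(np.unique(labels)) < 2:
                continue
            # Coarse grid scores force plenty of ties.
            proba = rng.integers(0, 4, size=(n, 3)) / 3.0
            assert macro_ovr_auc(labels, proba) == pytest.approx(
                brute_force_macro_ovr_auc(labels, proba), abs=1e-12
            )

    def test_matches_sklearn_on_clean_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            labels = rng.choice(CLASSES, size=60)
            if len(set(labels)) < 3:
                continue
            proba = rng.random((60, 3))
            proba /= proba.sum(axis=1, keepdims=True)
            ours = macro_ovr_auc(labels, proba)
            order = sorted(CLASSES)         # sklearn wants sorted labels
            ref = roc_auc_score(
                labels, proba[:, [CLASSES.index(c) for c in order]],
                multi_class="ovr", average="macro", labels=order,
            )
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_single_class_truth_undefined(self):
        labels = np.array(["Low", "Low"])
        with pytest.raises(ValueError):
            macro_ovr_auc(labels, np.ones((2, 3)) / 3)

    def test_absent_class_excluded_with_warning(self):
        labels = np.array(["Low", "Low", "Medium"])
        proba = np.array([[0.8, 0.1, 0.1], [0.7, 0.2, 0.1], [0.2, 0.7, 0.1]])
        with pytest.warns(UserWarning, match="High"):
            auc = macro_ovr_auc(labels, proba)
        assert auc == 1.0


class TestTrainAndPredict:
    def test_leakage_hard_failure(self, toy_table):
        with pytest.raises(LeakageError):
            train_and_predict(toy_table, toy_table.iloc[:3], FAST_RF,
                              ImbalanceStrategy())

    def test_single_class_training_gives_indicator(self):
        train = make_feature_table({"A": ["High"] * 8, "B": ["High"] * 8},
                                   RNG)
        test = make_feature_table({"C": ["Low", "High"]}, RNG)
        fold = train_and_predict(train, test, FAST_RF, ImbalanceStrategy())
        np.testing.assert_allclose(fold.probabilities[:, 2], 1.0)
        np.testing.assert_allclose(fold.probabilities[:, :2], 0.0)

    def test_probabilities_on_simplex(self, toy_table):
        splits = loso_splits(toy_table)
        _, train, test = splits[0]
        fold = train_and_predict(toy_table.loc[train], toy_table.loc[test],
                                 FAST_RF, ImbalanceStrategy("oversample"))
        np.testing.assert_allclose(fold.probabilities.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_separable_clusters_perfect_accuracy(self):
        # Two well-separated clusters per class, margins far above noise.
        rng = np.random.default_rng(9)
        train = make_feature_table(
            {"A": ["Low"] * 5 + ["Medium"] * 5 + ["High"] * 5,
             "B": ["Low"] * 5 + ["Medium"] * 5 + ["High"] * 5},
            rng, class_shift=25.0,
        )
        test = make_feature_table(
            {"C": ["Low"] * 4 + ["Medium"] * 3 + ["High"] * 3},
            rng, class_shift=25.0,
        )
        fold = train_and_predict(train, test, FAST_RF, ImbalanceStrategy())
        assert (fold.predicted_labels == test["label"].to_numpy()).all()

    def test_importances_normalized(self, toy_table):
        _, train, test = loso_splits(toy_table)[0]
        fold = train_and_predict(toy_table.loc[train], toy_table.loc[test],
                                 FAST_RF, ImbalanceStrategy())
        assert fold.feature_importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(fold.feature_importances) == 24


@pytest.fixture(scope="module")
def result(toy_table):
    return evaluate(toy_table, FAST_RF, ImbalanceStrategy("oversample"))


class TestEvaluate:

    def test_confusion_total_is_window_count(self, result, toy_table):
        assert result.confusion.to_numpy().sum() == len(toy_table)

    def test_fold_importances_sum_to_one(self, result):
        for fold in result.folds:
            assert fold.feature_importances.sum() == pytest.approx(
                1.0, abs=1e-9
            )

    def test_segment_percentages_sum_to_100(self, result):
        assert result.segment_importances.sum() == pytest.approx(
            100.0, abs=1e-6
        )
        assert set(result.segment_importances.index) == {
            "left_arm", "right_arm", "left_leg", "right_leg"
        }

    def test_test_folds_untouched_by_strategy(self, toy_table):
        none = evaluate(toy_table, FAST_RF, ImbalanceStrategy("none"))
        over = evaluate(toy_table, FAST_RF, ImbalanceStrategy("oversample"))
        for fa, fb in zip(none.folds, over.folds):
            assert fa.held_out_subject == fb.held_out_subject
            assert np.array_equal(fa.true_labels, fb.true_labels)

    def test_metrics_deterministic(self, toy_table):
        a = evaluate(toy_table, FAST_RF, ImbalanceStrategy("class_weight"))
        b = evaluate(toy_table, FAST_RF, ImbalanceStrategy("class_weight"))
        assert a.accuracy == b.accuracy
        assert a.macro_auc == b.macro_auc
        assert a.confusion.equals(b.confusion)

    def test_default_cohort_oversample_regression_guard(
        self, default_cohort_table
    ):
        # Regression floor for the full default cohort (n=10, seed 42)
        # under oversampling with the standard 500-tree forest.
        res = evaluate(default_cohort_table, RFConfig(),
                       ImbalanceStrategy("oversample"))
        assert res.accuracy > 0.6
        assert res.macro_auc > 0.8

    def test_macro_recall_from_confusion(self):
        y_true = np.array(["Low"] * 4 + ["Medium"] * 2 + ["High"] * 2)
        y_pred = np.array(["Low", "Low", "Medium", "Medium",
                           "Medium", "High", "High", "High"])
        # recalls: 2/4, 1/2, 2/2 -> macro 2/3.
        assert macro_recall(y_true, y_pred) == pytest.approx(2 / 3)
        cm = confusion_matrix(y_true, y_pred)
        assert cm.loc["Low", "Medium"] == 2
        assert cm.to_numpy().sum() == 8
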