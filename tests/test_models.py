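"""Classifier harness, importance extraction and the squared-sum weighted
importance aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearanx.exceptions import (
    DegenerateInputError,
    InvalidInputError,
    NotFittedError,
    SchemaError,
)
from wearanx.features import FEATURE_MODALITY
from wearanx.models import (
    AnxietyClassifier,
    ModelSpec,
    aggregate_importance,
    crossval_evaluate,
    feature_importances,
    importance_entropy,
    modality_rollup,
)


def brute_force_weighted_importance(matrix):
    """Independent double-loop implementation of the aggregation: square
    within model, sum across models, normalize by the total of the sums."""
    m = np.asarray(matrix, float)
    rows = np.array([row / row.sum() for row in m])
    n_models, n_feats = rows.shape
    s = [0.0] * n_feats
    for f in range(n_feats):
        for mod in range(n_models):
            s[f] += rows[mod][f] ** 2
    total = sum(s)
    return np.array([v / total for v in s])


class TestCrossval:
    def test_separable_clusters_high_accuracy(self, separable_table):
        for family in ("DT", "LDA"):
            res = crossval_evaluate(separable_table, ModelSpec(family=family),
                                    iters=1, compute_importance=False)
            assert res.mean_accuracy >= 0.95

    def test_shuffled_labels_near_chance(self, shuffled_table):
        res = crossval_evaluate(shuffled_table, ModelSpec(family="DT"),
                                iters=2, compute_importance=False)
        assert 0.4 <= res.mean_accuracy <= 0.6

    def test_deterministic_under_seed(self, separable_table):
        a = crossval_evaluate(separable_table, ModelSpec(family="RF", seed=3),
                              iters=1, compute_importance=False)
        b = crossval_evaluate(separable_table, ModelSpec(family="RF", seed=3),
                              iters=1, compute_importance=False)
        assert a.per_fold == b.per_fold
        assert a.mean_accuracy == b.mean_accuracy

    def test_mean_equals_fold_average(self, separable_table):
        res = crossval_evaluate(separable_table, ModelSpec(family="DT"),
                                iters=1, compute_importance=False)
        assert np.isclose(res.mean_accuracy,
                          np.mean([a for a, _ in res.per_fold]))
        assert np.isclose(res.mean_f1, np.mean([f for _, f in res.per_fold]))

    def test_too_few_rows_rejected(self, separable_table):
        with pytest.raises(InvalidInputError):
            crossval_evaluate(separable_table.head(10), ModelSpec(family="DT"))


class TestClassifierEstimator:
    def test_unfitted_predict_rejected(self):
        with pytest.raises(NotFittedError):
            AnxietyClassifier("DT").predict(np.zeros((3, 2)))

    def test_sklearn_param_interface(self):
        clf = AnxietyClassifier(family="KNN", seed=7)
        params = clf.get_params()
        assert params["family"] == "KNN" and params["seed"] == 7
        clf.set_params(family="SVM")
        assert clf.family == "SVM"

    def test_schema_enforced_by_name(self, separable_table):
        X = separable_table.drop(columns="label")
        y = separable_table["label"]
        clf = AnxietyClassifier("DT", seed=0).fit(X, y)
        with pytest.raises(SchemaError):
            clf.predict(X.rename(columns={"f0": "junk"}))


class TestImportance:
    def test_single_feature_normalizes_to_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"only": rng.normal(size=200)})
        y = (X["only"] > 0).astype(int)
        clf = AnxietyClassifier("LDA").fit(X, y)
        imp = feature_importances(clf)
        assert np.allclose(imp.to_numpy(), [1.0])

    def test_uninformative_feature_near_zero_permutation(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"signal": rng.normal(size=400),
                          "junk": rng.normal(size=400)})
        y = (X["signal"] > 0).astype(int)
        clf = AnxietyClassifier("KNN", seed=0).fit(X, y)
        imp = feature_importances(clf, X, y, n_repeats=20, seed=0)
        assert imp["junk"] < 0.05

    def test_duplicated_column_shares_tree_importance(self):
        rng = np.random.default_rng(2)
        base = pd.DataFrame({"a": rng.normal(size=500),
                             "b": rng.normal(size=500)})
        y = ((base["a"] + 0.3 * base["b"]) > 0).astype(int)
        clf1 = AnxietyClassifier("RF", seed=0).fit(base, y)
        single = feature_importances(clf1)
        dup = base.copy()
        dup["a2"] = base["a"]
        clf2 = AnxietyClassifier("RF", seed=0).fit(dup, y)
        shared = feature_importances(clf2)
        assert abs((shared["a"] + shared["a2"]) - single["a"]) < 0.05


class TestAggregation:
    def test_single_model_passthrough(self):
        w = aggregate_importance(np.array([[1.0, 0.0]]))
        assert np.allclose(w, [1.0, 0.0])

    def test_two_model_hand_example(self):
        m = np.array([[0.6, 0.4], [0.5, 0.5]])
        w = aggregate_importance(m)
        s = np.array([0.6 ** 2 + 0.5 ** 2, 0.4 ** 2 + 0.5 ** 2])
        assert np.allclose(w, s / s.sum())
        assert np.allclose(w, [0.61 / 1.02, 0.41 / 1.02])

    def test_uniform_importances_stay_uniform(self):
        m = np.full((3, 7), 1.0 / 7)
        assert np.allclose(aggregate_importance(m), 1.0 / 7)

    def test_weights_sum_to_one_and_match_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = rng.random((5, 10))
            w = aggregate_importance(m)
            assert np.isclose(w.sum(), 1.0)
            assert np.allclose(w, brute_force_weighted_importance(m),
                               atol=1e-12)

    @given(st.integers(0, 100))
    @settings(deadline=None, max_examples=30)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((4, 6)) + 0.01
        w = aggregate_importance(m)
        perm_f = rng.permutation(6)
        perm_m = rng.permutation(4)
        w_perm = aggregate_importance(m[perm_m][:, perm_f])
        assert np.allclose(w[perm_f], w_perm, atol=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            aggregate_importance(np.zeros((2, 3)))

    def test_dominant_feature_wins_aggregate(self):
        rng = np.random.default_rng(11)
        wins = 0
        for trial in range(20):
            X = pd.DataFrame(rng.normal(size=(300, 5)),
                             columns=list("abcde"))
            y = (X["c"] + 0.1 * rng.normal(size=300) > 0).astype(int)
            rows = []
            for fam in ("DT", "RF", "LDA"):
                clf = AnxietyClassifier(fam, seed=trial).fit(X, y)
                rows.append(feature_importances(clf))
            w = aggregate_importance(pd.DataFrame(rows))
            wins += int(w.idxmax() == "c")
        assert wins >= 18


class TestRollup:
    def test_addition_within_modality(self):
        w = pd.Series({"EDA_mean": 0.07, "EDA_drange": 0.06})
        out = modality_rollup(w, {"EDA_mean": "EDA", "EDA_drange": "EDA"})
        assert np.isclose(out["EDA"], 0.13)

    def test_single_modality_holds_all_weight(self):
        w = pd.Series({"TEMP_mean": 1.0})
        out = modality_rollup(w, FEATURE_MODALITY)
        assert np.isclose(out["TEMP"], 1.0)
        assert np.isclose(out.drop("TEMP").sum(), 0.0)

    def test_unmapped_feature_rejected(self):
        with pytest.raises(InvalidInputError):
            modality_rollup(pd.Series({"mystery": 1.0}), FEATURE_MODALITY)

    def test_entropy_of_uniform_weights(self):
        w = np.full(8, 1 / 8)
        assert np.isclose(importance_entropy(w), np.log(8))
        assert importance_entropy(np.array([1.0, 0.0])) == 0.0
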