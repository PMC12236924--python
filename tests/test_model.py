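import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from bulkqc.model import (fit_simplified_tree, importance_report, load_model, oob_auc,
                          predict_quality, rank_auc, save_model,
                          single_metric_logistic_auc, train_quality_forest)


def _separable(n=200, seed=0, n_noise=4):
    """Linearly separable toy cohort with a wide margin on one feature."""
    rng = np.random.default_rng(seed)
    y = np.array(["high"] * (n // 2) + ["low"] * (n - n // 2))
    x = np.where(y == "high", rng.normal(10, 1, n), rng.normal(-10, 1, n))
    feats = pd.DataFrame({"signal": x})
    for j in range(n_noise):
        feats[f"noise_{j}"] = rng.normal(0, 1, n)
    feats.index = [f"s{i}" for i in range(n)]
    return feats, pd.Series(y, index=feats.index)


class TestForestTraining:
    def test_separable_data_near_zero_oob_error(self):
        feats, labels = _separable()
        model = train_quality_forest(feats, labels, n_trees=200, seed=0)
        pred_high = model.oob_scores >= 0.5
        err = (pred_high != (labels == "high")).mean()
        assert err < 0.05
        assert model.oob_scores.between(0, 1).all()

    def test_deterministic_given_seed(self):
        feats, labels = _separable()
        m1 = train_quality_forest(feats, labels, n_trees=100, seed=5)
        m2 = train_quality_forest(feats, labels, n_trees=100, seed=5)
        pd.testing.assert_series_equal(m1.oob_scores, m2.oob_scores)

    def test_permuted_labels_give_chance_auc(self):
        feats, labels = _separable(n=300, seed=1)
        perm = pd.Series(np.random.default_rng(2).permutation(labels.to_numpy()),
                         index=labels.index)
        model = train_quality_forest(feats, perm, n_trees=200, seed=1)
        assert abs(oob_auc(model) - 0.5) < 0.12

    def test_single_class_labels_rejected(self):
        feats, labels = _separable(n=20)
        with pytest.raises(ValueError, match="class"):
            train_quality_forest(feats, pd.Series("high", index=feats.index))


class TestAUC:
    def test_perfectly_ordered_scores(self):
        assert rank_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 1.0
        assert rank_auc([0.9, 0.8, 0.2, 0.1], [False, False, True, True]) == 0.0

    def test_matches_pairwise_concordance_and_sklearn(self, rng):
        scores = rng.uniform(0, 1, 50)
        labels = rng.uniform(0, 1, 50) > 0.6
        # O(n^2) Mann-Whitney concordance count
        num = sum((1.0 if sp > sn else 0.5 if sp == sn else 0.0)
                  for sp in scores[labels] for sn in scores[~labels])
        expected = num / (labels.sum() * (~labels).sum())
        assert rank_auc(scores, labels) == pytest.approx(expected)
        assert rank_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            rank_auc([0.1, 0.2], [True, True])


class TestLogisticBaseline:
    def test_metric_identical_to_label_scores_one(self):
        labels = pd.Series(["high"] * 30 + ["low"] * 30)
        metric = pd.Series([1.0] * 30 + [0.0] * 30)
        assert single_metric_logistic_auc(metric, labels, seed=0) == 1.0

    def test_independent_metric_scores_near_half(self):
        rng = np.random.default_rng(4)
        labels = pd.Series(np.where(rng.uniform(size=500) < 0.2, "low", "high"))
        metric = pd.Series(rng.normal(0, 1, 500))
        auc = single_metric_logistic_auc(metric, labels, seed=0)
        assert abs(auc - 0.5) < 0.1

    def test_deterministic_given_seed(self, cohort_features, truth_labels):
        a = single_metric_logistic_auc(cohort_features["n_detected_genes"],
                                       truth_labels, seed=3)
        b = single_metric_logistic_auc(cohort_features["n_detected_genes"],
                                       truth_labels, seed=3)
        assert a == b


class TestImportance:
    def test_planted_signal_tops_all_three_columns(self):
        feats, labels = _separable(n=200, seed=2, n_noise=7)
        model = train_quality_forest(feats, labels, n_trees=150, seed=2)
        rep = importance_report(model, feats, n_intervals=20)
        assert rep["gini_importance"].idxmax() == "signal"
        assert rep["selection_frequency"].idxmax() == "signal"
        assert rep["ale_importance"].idxmax() == "signal"
        assert rep["selection_frequency"].between(0, 1).all()
        assert (rep >= 0).all().all()

    def test_all_noise_features_have_no_dominant_column(self):
        rng = np.random.default_rng(6)
        feats = pd.DataFrame(rng.normal(size=(200, 6)),
                             columns=[f"n{j}" for j in range(6)])
        labels = pd.Series(np.where(rng.uniform(size=200) < 0.5, "low", "high"),
                           index=feats.index)
        model = train_quality_forest(feats, labels, n_trees=150, seed=6)
        rep = importance_report(model, feats, n_intervals=10)
        for col in ["gini_importance", "ale_importance"]:
            assert rep[col].max() / rep[col].median() < 3


class TestPrediction:
    def test_training_cohort_as_external_gives_full_ensemble_auc(self):
        feats, labels = _separable()
        model = train_quality_forest(feats, labels, n_trees=100, seed=0)
        scores = predict_quality(model, feats)
        assert scores.between(0, 1).all()
        # full ensemble differs from OOB but both discriminate perfectly here
        assert rank_auc(scores, (labels == "high")) == 1.0

    def test_schema_mismatch_names_missing_columns(self):
        feats, labels = _separable(n=40)
        model = train_quality_forest(feats, labels, n_trees=50, seed=0)
        with pytest.raises(ValueError, match="signal"):
            predict_quality(model, feats.drop(columns=["signal"]))

    def test_save_load_roundtrip(self, tmp_path):
        feats, labels = _separable(n=60)
        model = train_quality_forest(feats, labels, n_trees=50, seed=0)
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        pd.testing.assert_series_equal(back.oob_scores, model.oob_scores)
        pd.testing.assert_series_equal(predict_quality(back, feats),
                                       predict_quality(model, feats))


class TestSimplifiedTree:
    def test_separable_one_dimension_depth_one_perfect(self):
        feats, labels = _separable(n=80, n_noise=0)
        tree, rep = fit_simplified_tree(feats, labels, max_depth=1)
        assert rep["train_accuracy"] == 1.0
        assert tree.get_depth() == 1

    def test_predictions_match_manual_traversal(self, rng):
        feats, labels = _separable(n=150, seed=3)
        tree, _ = fit_simplified_tree(feats, labels, max_depth=3)
        rows = pd.DataFrame(rng.normal(0, 8, size=(100, feats.shape[1])),
                            columns=feats.columns)
        t = tree.tree_
        manual = []
        for _, row in rows.iterrows():
            node = 0
            while t.children_left[node] != -1:
                f, thr = t.feature[node], t.threshold[node]
                node = (t.children_left[node] if row.iloc[f] <= thr
                        else t.children_right[node])
            manual.append(int(np.argmax(t.value[node, 0])))
        np.testing.assert_array_equal(tree.predict(rows.to_numpy()), manual)

    def test_test_set_accuracy_reported(self):
        feats, labels = _separable(n=100)
        tf, tl = _separable(n=40, seed=9)
        _, rep = fit_simplified_tree(feats, labels, max_depth=2,
                                     test_features=tf, test_labels=tl)
        assert rep["test_accuracy"] == 1.0
        assert {"feature", "threshold", "n_low", "n_high"} <= set(rep["nodes"].columns)
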