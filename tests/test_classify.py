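"""Classifier training, confusion-matrix metrics, and ROC analysis."""

import numpy as np
import pandas as pd
import pytest

from oracles import auc_pairwise_oracle
from pulseaf import (
    AFDetector,
    ConfigurationError,
    SplitSpec,
    build_feature_table,
    evaluate_classifier,
    generate_dataset,
    roc_curve_points,
    train_classifier,
)


def separable_table(rng, n=80):
    vt = np.repeat([0, 1], n // 2)
    x = vt * 10.0 + rng.normal(0, 0.1, size=n)
    return pd.DataFrame({"feat": x, "other": rng.normal(size=n), "Vt": vt})


@pytest.fixture(scope="module")
def small_cohort_table():
    records = generate_dataset(5, seed=77)
    return build_feature_table([(w, t) for w, t in records])


class TestBuildFeatureTable:
    def test_group1_column_structure(self, small_cohort_table):
        assert small_cohort_table.shape == (10, 28)
        assert list(small_cohort_table.columns)[-1] == "Vt"

    def test_group3_has_12_columns(self):
        records = generate_dataset(3, seed=78)
        table = build_feature_table([(w, t) for w, t in records], group="Group3")
        assert table.shape[1] == 12

    def test_labels_preserved(self, small_cohort_table):
        af_rows = [rid for rid in small_cohort_table.index if str(rid).startswith("af")]
        assert (small_cohort_table.loc[af_rows, "Vt"] == 1).all()
        assert small_cohort_table["Vt"].sum() == 5


class TestTrainClassifier:
    def test_separable_table_classified_perfectly(self, rng):
        result = train_classifier(separable_table(rng), split=SplitSpec(seed=0))
        report = evaluate_classifier(result.labels, result.scores)
        assert report.accuracy == 1.0

    @pytest.mark.parametrize("model", ["gradient_boosting", "adaboost", "xgboost"])
    def test_deterministic_given_seed(self, rng, model):
        table = separable_table(rng)
        a = train_classifier(table, model=model, split=SplitSpec(seed=3))
        b = train_classifier(table, model=model, split=SplitSpec(seed=3))
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.labels, b.labels)

    def test_kfold_scheme_pools_all_rows(self, rng):
        table = separable_table(rng)
        result = train_classifier(table, split=SplitSpec(scheme="kfold", folds=4, seed=0))
        assert result.labels.size == len(table)

    def test_single_class_rejected(self, rng):
        table = separable_table(rng)
        table["Vt"] = 0
        with pytest.raises(ConfigurationError):
            train_classifier(table)

    def test_unknown_model_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            train_classifier(separable_table(rng), model="perceptron")

    def test_detector_sklearn_contract(self, rng):
        from sklearn.base import clone

        table = separable_table(rng)
        det = AFDetector(model="gradient_boosting", random_state=1)
        det2 = clone(det)
        assert det2.get_params() == det.get_params()
        x, y = table[["feat", "other"]], table["Vt"].to_numpy()
        det.fit(x, y)
        assert hasattr(det, "estimator_") and det.classes_.tolist() == [0, 1]
        assert det.predict(x).shape == y.shape
        assert np.all((det.decision_scores(x) >= 0) & (det.decision_scores(x) <= 1))


class TestEvaluateClassifier:
    def test_perfect_scores(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.9, 0.8])
        report = evaluate_classifier(labels, scores)
        assert (report.sensitivity, report.specificity, report.accuracy, report.roc_auc) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_hand_computed_confusion_fractions(self):
        # TP=50, FN=1, TN=60, FP=2
        labels = np.concatenate([np.ones(51), np.zeros(62)])
        scores = np.concatenate([np.full(50, 0.9), [0.1], np.full(60, 0.1), np.full(2, 0.9)])
        report = evaluate_classifier(labels, scores)
        assert (report.tp, report.fp, report.tn, report.fn) == (50, 2, 60, 1)
        assert np.isclose(report.sensitivity, 50 / 51)
        assert np.isclose(report.specificity, 60 / 62)
        assert np.isclose(report.accuracy, 110 / 113)
        assert np.isclose(report.precision, 50 / 52)
        p, s = 50 / 52, 50 / 51
        assert np.isclose(report.f_score, 2 * p * s / (p + s))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=25)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=25), 1)  # coarse grid forces ties
        report = evaluate_classifier(labels, scores)
        assert np.isclose(report.roc_auc, auc_pairwise_oracle(labels, scores), rtol=1e-9)

    def test_accuracy_prevalence_identity(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=40)
        r = evaluate_classifier(labels, scores)
        p, n = labels.sum(), (1 - labels).sum()
        assert np.isclose(r.accuracy, (r.sensitivity * p + r.specificity * n) / (p + n))

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=30)
        a = evaluate_classifier(labels, scores).roc_auc
        b = evaluate_classifier(labels, np.exp(3 * scores)).roc_auc
        assert np.isclose(a, b)

    def test_label_flip_swaps_sensitivity_specificity_and_auc(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=30)
        r1 = evaluate_classifier(labels, scores)
        r2 = evaluate_classifier(1 - labels, 1 - scores + 1e-12)
        assert np.isclose(r1.sensitivity, r2.specificity)
        assert np.isclose(r1.specificity, r2.sensitivity)
        r3 = evaluate_classifier(1 - labels, scores)
        assert np.isclose(r3.roc_auc, 1 - r1.roc_auc)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError, match="single class"):
            evaluate_classifier(np.ones(5), np.random.uniform(size=5))


class TestRocCurve:
    def test_constant_scores_give_diagonal(self):
        labels = np.array([0, 1, 0, 1])
        pts = roc_curve_points(labels, np.full(4, 0.5))
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]
        assert np.isclose(evaluate_classifier(labels, np.full(4, 0.5)).roc_auc, 0.5)

    def test_perfect_separation_passes_through_corner(self):
        pts = roc_curve_points([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert any(np.allclose(p, [0.0, 1.0]) for p in pts)

    def test_monotone_nondecreasing(self, rng):
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        pts = roc_curve_points(labels, rng.uniform(size=20))
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
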