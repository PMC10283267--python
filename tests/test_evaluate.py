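"""Classifier roster, split, cross-validation, selection, metrics."""

import numpy as np
import pandas as pd
import pytest

from clinselect import (
    TaskConfig,
    bundle_from_report,
    cross_validate_roster,
    default_roster,
    evaluate_task,
    fast_roster,
    load_model,
    persist_model,
    select_best,
    split_train_validation,
)
from clinselect.evaluate import EvaluationError, metrics_from_confusion, _target_labels
from clinselect.preprocess import ImputationStrategy


EXPECTED_ROSTER = [
    "logistic_regression", "svm_linear", "svm_rbf", "sgd_linear",
    "gaussian_nb", "bernoulli_nb", "gaussian_process", "mlp",
    "decision_tree", "random_forest", "xgboost", "adaboost", "stacking",
]


class TestRoster:
    def test_thirteen_members_fixed_order(self):
        roster = default_roster(0)
        assert [s.id for s in roster] == EXPECTED_ROSTER
        assert [s.id for s in default_roster(123)] == EXPECTED_ROSTER

    def test_hyperparameters_frozen_across_calls(self):
        a = {s.id: s.params for s in default_roster(1)}
        b = {s.id: s.params for s in default_roster(1)}
        assert a == b

    def test_seed_only_touches_stochastic_fields(self):
        a = {s.id: s.params for s in default_roster(1)}
        b = {s.id: s.params for s in default_roster(2)}
        assert a == b  # the seed is applied at build time, not in the frozen params


class TestSplit:
    def test_230_rows_80_20_gives_184_46(self, sim230):
        table, schema, _ = sim230
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=3)
        train, val = split_train_validation(table, config)
        assert (train.n_rows, val.n_rows) == (184, 46)

    def test_partition_disjoint_and_exhaustive(self, sim230):
        table, _, _ = sim230
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=3)
        train, val = split_train_validation(table, config)
        tr, va = set(train.values.index), set(val.values.index)
        assert tr.isdisjoint(va)
        assert tr | va == set(table.values.index)

    def test_stratified_within_one_sample(self, sim230):
        table, _, _ = sim230
        for seed in range(5):
            config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=seed)
            train, val = split_train_validation(table, config)
            y = _target_labels(table, "SecondSedation")
            overall = y.mean()
            for part in (train, val):
                yp = _target_labels(part, "SecondSedation")
                assert abs(yp.sum() - overall * len(yp)) <= 1.0


class TestCrossValidation:
    def test_separable_data_reaches_perfect_score(self, roster2):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": np.r_[rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1, 30)]})
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        config = TaskConfig(target="t", class_of_interest=1, seed=0)
        scores = cross_validate_roster(X, y, roster2, config)
        assert len(scores) == len(roster2)
        assert all(len(v) == 3 for v in scores.values())
        assert max(float(np.mean(v)) for v in scores.values()) == 1.0

    def test_class_rarer_than_folds_rejected(self, roster2):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = np.array([0] * 8 + [1] * 2)
        config = TaskConfig(target="t", class_of_interest=1, seed=0, cv_folds=3)
        with pytest.raises(EvaluationError, match="fewer than cv_folds"):
            cross_validate_roster(X, y, roster2, config)


class TestSelection:
    def test_max_mean_wins(self, roster2):
        scores = {"logistic_regression": [0.9, 0.9, 0.9], "decision_tree": [0.8, 0.8, 0.8]}
        assert select_best(scores, roster2) == "logistic_regression"

    def test_tie_breaks_by_roster_order(self, roster2):
        scores = {"logistic_regression": [0.8], "decision_tree": [0.8]}
        assert select_best(scores, roster2) == "logistic_regression"

    def test_multiclass_selection_uses_macro_mean(self):
        from clinselect.evaluate import _selection_score

        config = TaskConfig(target="t", metric="f1", seed=0)
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 0, 1, 0, 1, 1])  # class 0: f1 varies; macro = mean
        classes = np.array([0, 1, 2])
        from sklearn.metrics import f1_score

        expected = f1_score(y_true, y_pred, average="macro")
        assert _selection_score(y_true, y_pred, config, classes) == pytest.approx(expected)


class TestMetricsFromConfusion:
    def test_worked_binary_example(self):
        # rows = true class, cols = predicted: [[10, 1], [2, 3]]
        derived = metrics_from_confusion(np.array([[10, 1], [2, 3]]), [0, 1])
        assert derived["per_class"]["precision"][1] == pytest.approx(0.75)
        assert derived["per_class"]["recall"][1] == pytest.approx(0.6)
        assert derived["per_class"]["f1"][1] == pytest.approx(2 / 3, abs=1e-4)

    def test_macro_and_balanced_identities(self):
        conf = np.array([[8, 2, 0], [1, 5, 1], [0, 2, 6]])
        derived = metrics_from_confusion(conf, [0, 1, 2])
        assert derived["macro"]["f1"] == pytest.approx(np.mean(list(derived["per_class"]["f1"].values())))
        assert derived["balanced_accuracy"] == pytest.approx(np.mean(list(derived["per_class"]["recall"].values())))

    def test_perfect_predictor(self):
        derived = metrics_from_confusion(np.diag([7, 5]), [0, 1])
        assert derived["macro"]["precision"] == derived["macro"]["recall"] == 1.0
        assert derived["balanced_accuracy"] == 1.0


class TestEvaluateTask:
    def test_deterministic_reports_under_fixed_seed(self, small_signal, roster2):
        table, schema, _ = small_signal
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=5)
        preds = ["Bin2", "Num1", "Cont1"]
        r1 = evaluate_task(table, schema, preds, config, roster2)
        r2 = evaluate_task(table, schema, preds, config, roster2)
        assert r1.to_json() == r2.to_json()

    def test_report_shape_and_invariants(self, small_signal, roster2):
        table, schema, _ = small_signal
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=5)
        report = evaluate_task(table, schema, ["Bin2", "Num1", "Cont1"], config, roster2)
        assert set(report.cv_scores) == {s.id for s in roster2}
        means = {k: float(np.mean(v)) for k, v in report.cv_scores.items()}
        assert report.selection_score == max(means.values())
        conf = np.array(report.result.confusion)
        assert conf.sum() == round(0.2 * table.n_rows)
        proba = np.array(report.result.probabilities)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert len(report.per_sample) == conf.sum()

    def test_full_roster_runs_and_probabilities_calibrated(self, small_signal):
        """Every roster member (including calibrated SVM/SGD wrappers)
        fits and emits probabilities in [0, 1] summing to 1."""
        table, schema, _ = small_signal
        sub = table.take_rows(table.values.index[:120])
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=5)
        report = evaluate_task(sub, schema, ["Bin2", "Num1"], config, default_roster(5))
        assert len(report.cv_scores) == 13
        proba = np.array(report.result.probabilities)
        assert (proba >= 0).all() and (proba <= 1).all()
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_strong_signal_reaches_high_f1(self, roster2):
        """With three 2.5 log-odds planted effects the winning model
        should predict the class of interest with validation f1 >= 0.8."""
        from clinselect.simulate import generate_case_study_like, strong_signal_spec

        table, schema = generate_case_study_like(strong_signal_spec(seed=5))
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=5)
        preds = ["Bin2", "Num1", "Cont1"]
        report = evaluate_task(table, schema, preds, config, roster2)
        assert report.result.per_class["f1"][1] >= 0.8 - 1e-9  # float-repr slack only


class TestPersistence:
    def test_round_trip_predictions_identical(self, small_signal, roster2, tmp_path):
        table, schema, _ = small_signal
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=5)
        report = evaluate_task(table, schema, ["Bin2", "Num1", "ListTeeth1"], config, roster2)
        path = tmp_path / "model.zip"
        bundle = persist_model(report, path, roster2)
        loaded = load_model(path)
        assert loaded.predictors == bundle.predictors  # self-describing
        p1 = bundle.predict_proba(table)
        p2 = loaded.predict_proba(table)
        assert np.array_equal(p1, p2)

    def test_missing_predictor_named_on_load_mismatch(self, small_signal, roster2, tmp_path):
        table, schema, _ = small_signal
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=5)
        report = evaluate_task(table, schema, ["Bin2", "Num1"], config, roster2)
        bundle = bundle_from_report(report, roster2)
        crippled = table.take_rows(table.values.index)
        crippled.values.drop(columns=["Num1"], inplace=True)
        crippled.missing_mask.drop(columns=["Num1"], inplace=True)
        with pytest.raises(EvaluationError, match="Num1"):
            bundle.predict_proba(crippled)
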