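"""Classifier-evaluation workflow.

Given a typed table, a target and a predictor set, the engine

1. resolves missing targets with the configured imputation strategy,
2. draws one stratified 80/20 train/validation split,
3. cross-validates a fixed 13-member classifier roster (3 stratified
   folds by default) on the training part,
4. selects the best roster member by the chosen per-class metric
   (class of interest for binary targets, macro average otherwise;
   ties go to the earlier roster position),
5. refits the winner on the full training set — wrapping it in
   cross-validated sigmoid (Platt) calibration when its raw scores are
   not probabilities — and scores it on the held-out validation set,
6. packages everything (schema, transform plan, fitted model, config,
   background rows for explanations) into a persistable model bundle.

All randomness flows from ``TaskConfig.seed``; two runs with the same
seed produce identical reports.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Any, Callable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    AdaBoostClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .preprocess import (
    ImputationStrategy,
    TransformPlan,
    apply_transform,
    build_transform_plan,
    impute_target,
)
from .schema import ClinicalTable, DatasetSchema, schema_from_dict, schema_to_dict

ROSTER_VERSION = "1.0"
METRICS = ("precision", "recall", "f1")
#: Cap on background rows stored in a bundle for explanation purposes.
BACKGROUND_LIMIT = 1000


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Task configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskConfig:
    """User-facing knobs of one evaluation task."""

    target: str
    class_of_interest: int | None = None
    metric: str = "f1"
    validation_fraction: float = 0.2
    cv_folds: int = 3
    seed: int = 0
    imputation: ImputationStrategy = field(default_factory=lambda: ImputationStrategy("drop_rows"))
    encode_categoricals: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise EvaluationError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise EvaluationError("validation_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise EvaluationError("cv_folds must be at least 2")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "class_of_interest": self.class_of_interest,
            "metric": self.metric,
            "validation_fraction": self.validation_fraction,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "imputation": {"mode": self.imputation.mode, "constant_value": self.imputation.constant_value},
            "encode_categoricals": self.encode_categoricals,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TaskConfig":
        imp = d.get("imputation", {"mode": "drop_rows", "constant_value": None})
        return cls(
            target=d["target"],
            class_of_interest=d.get("class_of_interest"),
            metric=d.get("metric", "f1"),
            validation_fraction=d.get("validation_fraction", 0.2),
            cv_folds=d.get("cv_folds", 3),
            seed=d.get("seed", 0),
            imputation=ImputationStrategy(imp["mode"], imp.get("constant_value")),
            encode_categoricals=d.get("encode_categoricals", True),
        )


# ---------------------------------------------------------------------------
# The classifier roster
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierSpec:
    """One roster member: identifier, family and frozen hyperparameters."""

    id: str
    family: str
    params: tuple[tuple[str, Any], ...]
    probabilistic: bool  # raw scores already behave as probabilities
    builder: Callable[[int, Mapping[str, Any]], Any]

    def build(self, seed: int):
        return self.builder(seed, dict(self.params))

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "family": self.family,
            "params": {k: v for k, v in self.params},
            "probabilistic": self.probabilistic,
        }


def _spec(id_, family, params, probabilistic, builder):
    return ClassifierSpec(id_, family, tuple(sorted(params.items())), probabilistic, builder)


def default_roster(seed: int = 0) -> list[ClassifierSpec]:
    """The fixed 13-member roster, in evaluation (and tie-break) order.

    Hyperparameters are frozen package defaults; only stochastic
    initialization depends on the seed.  Hyperparameter search is a
    deliberate non-feature.
    """
    return [
        _spec("logistic_regression", "linear", {"max_iter": 2000},
              True, lambda s, p: LogisticRegression(**p)),
        _spec("svm_linear", "svm", {"kernel": "linear", "C": 1.0},
              False, lambda s, p: SVC(**p)),
        _spec("svm_rbf", "svm", {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
              False, lambda s, p: SVC(**p)),
        _spec("sgd_linear", "linear", {"loss": "hinge", "alpha": 1e-4},
              False, lambda s, p: SGDClassifier(random_state=s, **p)),
        _spec("gaussian_nb", "naive_bayes", {},
              True, lambda s, p: GaussianNB(**p)),
        _spec("bernoulli_nb", "naive_bayes", {},
              True, lambda s, p: BernoulliNB(**p)),
        _spec("gaussian_process", "gaussian_process", {},
              True, lambda s, p: GaussianProcessClassifier(random_state=s, **p)),
        _spec("mlp", "neural_network", {"hidden_layer_sizes": (100,), "max_iter": 600},
              True, lambda s, p: MLPClassifier(random_state=s, **p)),
        _spec("decision_tree", "tree", {"max_depth": 5},
              True, lambda s, p: DecisionTreeClassifier(random_state=s, **p)),
        _spec("random_forest", "ensemble_tree", {"n_estimators": 100, "max_depth": 6},
              True, lambda s, p: RandomForestClassifier(random_state=s, **p)),
        _spec("xgboost", "ensemble_tree", {"n_estimators": 100, "max_depth": 4},
              True, lambda s, p: XGBClassifier(random_state=s, eval_metric="logloss", **p)),
        _spec("adaboost", "ensemble_tree", {"n_estimators": 50},
              True, lambda s, p: AdaBoostClassifier(random_state=s, **p)),
        _spec("stacking", "ensemble", {},
              True, lambda s, p: StackingClassifier(
                  estimators=[
                      ("random_forest", RandomForestClassifier(n_estimators=100, max_depth=6, random_state=s)),
                      ("gaussian_process", GaussianProcessClassifier(random_state=s)),
                      ("logistic_regression", LogisticRegression(max_iter=2000)),
                  ],
                  final_estimator=LogisticRegression(max_iter=2000),
              )),
    ]


def fast_roster(seed: int = 0) -> list[ClassifierSpec]:
    """Reduced roster (logistic regression + decision tree) for large
    feature-search sweeps where fitting all 13 members per subset would
    dominate the runtime."""
    roster = default_roster(seed)
    keep = {"logistic_regression", "decision_tree"}
    return [s for s in roster if s.id in keep]


def roster_by_id(roster: Sequence[ClassifierSpec], id_: str) -> ClassifierSpec:
    for s in roster:
        if s.id == id_:
            return s
    raise EvaluationError(f"unknown classifier id {id_!r}")


# ---------------------------------------------------------------------------
# Split / CV / selection
# ---------------------------------------------------------------------------


def _target_labels(table: ClinicalTable, target: str) -> np.ndarray:
    col = table.values[target]
    if table.missing_mask[target].any():
        raise EvaluationError(f"target {target!r} still has missing values; impute first")
    return np.asarray([int(v) for v in col])


def split_train_validation(table: ClinicalTable, config: TaskConfig) -> tuple[ClinicalTable, ClinicalTable]:
    """Stratified partition; |validation| = round(fraction * n)."""
    y = _target_labels(table, config.target)
    n = len(y)
    n_val = int(round(config.validation_fraction * n))
    if n_val < 1 or n_val >= n:
        raise EvaluationError("validation fraction leaves an empty partition")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise EvaluationError(f"class {classes[counts.argmin()]} too rare to stratify")
    idx = np.arange(n)
    train_idx, val_idx = train_test_split(
        idx, test_size=n_val, stratify=y, random_state=config.seed, shuffle=True
    )
    train_idx.sort()
    val_idx.sort()
    rows = table.values.index.to_numpy()
    return table.take_rows(rows[train_idx]), table.take_rows(rows[val_idx])


def _per_class_scores(y_true, y_pred, classes) -> dict[str, dict[int, float]]:
    p, r, f, _ = precision_recall_fscore_support(y_true, y_pred, labels=classes, zero_division=0)
    return {
        "precision": {int(c): float(v) for c, v in zip(classes, p)},
        "recall": {int(c): float(v) for c, v in zip(classes, r)},
        "f1": {int(c): float(v) for c, v in zip(classes, f)},
    }


def _selection_score(y_true, y_pred, config: TaskConfig, classes) -> float:
    """Per-fold score: chosen metric on the class of interest (binary)
    or its macro average (multiclass)."""
    scores = _per_class_scores(y_true, y_pred, classes)[config.metric]
    if len(classes) == 2:
        coi = config.class_of_interest
        if coi is None:
            raise EvaluationError("class_of_interest is required for binary targets")
        if int(coi) not in scores:
            raise EvaluationError(f"class_of_interest {coi} not among target classes {list(scores)}")
        return scores[int(coi)]
    return float(np.mean(list(scores.values())))


def cross_validate_roster(
    X: pd.DataFrame,
    y: np.ndarray,
    roster: Sequence[ClassifierSpec],
    config: TaskConfig,
) -> dict[str, list[float]]:
    """One score per (classifier, stratified fold); deterministic under seed."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EvaluationError("training labels contain a single class")
    if counts.min() < config.cv_folds:
        raise EvaluationError(
            f"class {int(classes[counts.argmin()])} has {int(counts.min())} members, fewer than cv_folds={config.cv_folds}"
        )
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    Xa = np.asarray(X, dtype=float)
    y_enc = np.searchsorted(classes, y)  # 0..K-1, required by some libraries
    folds = list(skf.split(Xa, y_enc))
    scores: dict[str, list[float]] = {}
    for spec in roster:
        fold_scores = []
        for tr, te in folds:
            model = spec.build(config.seed)
            model.fit(Xa[tr], y_enc[tr])
            y_pred = classes[model.predict(Xa[te])]
            fold_scores.append(_selection_score(y[te], y_pred, config, classes))
        scores[spec.id] = fold_scores
    return scores


def select_best(cv_scores: Mapping[str, Sequence[float]], roster: Sequence[ClassifierSpec]) -> str:
    """Roster member with the highest fold-mean score; ties break toward
    the earlier roster position."""
    best_id, best_mean = None, -np.inf
    for spec in roster:
        mean = float(np.mean(cv_scores[spec.id]))
        if mean > best_mean:
            best_id, best_mean = spec.id, mean
    assert best_id is not None
    return best_id


# ---------------------------------------------------------------------------
# Fit, calibrate, validate
# ---------------------------------------------------------------------------


@dataclass
class ClassifierResult:
    """Validation-set scorecard of one fitted classifier."""

    classifier_id: str
    classes: list[int]
    confusion: list[list[int]]
    per_class: dict[str, dict[int, float]]
    macro: dict[str, float]
    balanced_accuracy: float
    roc_auc: float | None
    predicted: list[int]
    probabilities: list[list[float]]

    def to_dict(self) -> dict:
        return {
            "classifier_id": self.classifier_id,
            "classes": self.classes,
            "confusion_matrix": self.confusion,
            "per_class": {m: {str(c): v for c, v in d.items()} for m, d in self.per_class.items()},
            "macro": self.macro,
            "balanced_accuracy": self.balanced_accuracy,
            "roc_auc": self.roc_auc,
            "predicted": self.predicted,
            "probabilities": self.probabilities,
        }


def _fit_calibrated(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, config: TaskConfig):
    """Fit on the full training set; non-probabilistic scorers get
    cross-validated sigmoid (Platt) calibration fitted on training data."""
    base = spec.build(config.seed)
    if spec.probabilistic:
        model = base
    else:
        _, counts = np.unique(y, return_counts=True)
        cv = min(config.cv_folds, int(counts.min()))
        model = CalibratedClassifierCV(base, method="sigmoid", cv=cv)
    model.fit(X, y)
    return model


def metrics_from_confusion(confusion: np.ndarray, classes: Sequence[int]) -> dict:
    """Precision / recall / f1 per class plus macro averages and balanced
    accuracy, derived purely from a confusion matrix (rows = true class)."""
    confusion = np.asarray(confusion, dtype=float)
    per_class: dict[str, dict[int, float]] = {"precision": {}, "recall": {}, "f1": {}}
    for j, c in enumerate(classes):
        tp = confusion[j, j]
        fp = confusion[:, j].sum() - tp
        fn = confusion[j, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class["precision"][int(c)] = float(prec)
        per_class["recall"][int(c)] = float(rec)
        per_class["f1"][int(c)] = float(f1)
    macro = {m: float(np.mean(list(d.values()))) for m, d in per_class.items()}
    balanced = float(np.mean(list(per_class["recall"].values())))
    return {"per_class": per_class, "macro": macro, "balanced_accuracy": balanced}


def fit_and_validate(
    spec: ClassifierSpec,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_val: pd.DataFrame,
    y_val: np.ndarray,
    config: TaskConfig,
):
    """Train the selected classifier on the full training set and score it
    on the held-out validation set.  Returns (result, fitted_model)."""
    classes = np.unique(y_train)
    y_enc = np.searchsorted(classes, y_train)
    model = _fit_calibrated(spec, np.asarray(X_train, dtype=float), y_enc, config)
    Xv = np.asarray(X_val, dtype=float)
    y_pred = classes[model.predict(Xv)]
    proba = model.predict_proba(Xv)  # columns follow encoded order = sorted classes
    conf = confusion_matrix(y_val, y_pred, labels=classes)
    derived = metrics_from_confusion(conf, classes)
    auc: float | None
    present = np.unique(y_val)
    if len(present) < len(classes):
        auc = None  # validation misses a class entirely
    elif len(classes) == 2:
        coi = int(config.class_of_interest)
        coi_col = int(np.flatnonzero(classes == coi)[0])
        auc = float(roc_auc_score((y_val == coi).astype(int), proba[:, coi_col]))
    else:
        y_val_enc = np.searchsorted(classes, y_val)
        auc = float(roc_auc_score(y_val_enc, proba, multi_class="ovr", average="macro"))
    result = ClassifierResult(
        classifier_id=spec.id,
        classes=[int(c) for c in classes],
        confusion=conf.astype(int).tolist(),
        per_class=derived["per_class"],
        macro=derived["macro"],
        balanced_accuracy=derived["balanced_accuracy"],
        roc_auc=auc,
        predicted=[int(v) for v in y_pred],
        probabilities=[[float(p) for p in row] for row in proba],
    )
    return result, model


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    config: TaskConfig
    predictors: list[str]
    cv_scores: dict[str, list[float]]
    best_id: str
    selection_score: float
    result: ClassifierResult
    per_sample: pd.DataFrame
    plan: TransformPlan
    model: Any
    schema: DatasetSchema
    train_matrix: pd.DataFrame
    y_train: np.ndarray

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "predictors": self.predictors,
            "cv_scores": self.cv_scores,
            "cv_means": {k: float(np.mean(v)) for k, v in self.cv_scores.items()},
            "best_classifier": self.best_id,
            "selection_score": self.selection_score,
            "validation": self.result.to_dict(),
            "per_sample": self.per_sample.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def prepare_task(table: ClinicalTable, schema: DatasetSchema, predictors: Sequence[str], config: TaskConfig):
    """Shared front half of evaluation: impute target, split, fit the
    transform plan on train, encode both partitions.

    Returns (plan, X_train, y_train, X_val, y_val, train_table, val_table).
    The split depends only on the target labels and the seed, never on
    the predictor subset — so feature-subset scores are comparable.
    """
    predictors = list(predictors)
    if config.target in predictors:
        raise EvaluationError("target cannot appear among predictors")
    table = impute_target(table, config.target, config.imputation, schema)
    train, val = split_train_validation(table, config)
    plan = build_transform_plan(train, schema, predictors, encode_categoricals=config.encode_categoricals)
    X_train = apply_transform(plan, train, schema)
    X_val = apply_transform(plan, val, schema)
    y_train = _target_labels(train, config.target)
    y_val = _target_labels(val, config.target)
    return plan, X_train, y_train, X_val, y_val, train, val


def evaluate_task(
    table: ClinicalTable,
    schema: DatasetSchema,
    predictors: Sequence[str],
    config: TaskConfig,
    roster: Sequence[ClassifierSpec] | None = None,
) -> EvaluationReport:
    """The full classifier-evaluation workflow (see module docstring)."""
    roster = list(roster) if roster is not None else default_roster(config.seed)
    plan, X_train, y_train, X_val, y_val, train, val = prepare_task(table, schema, predictors, config)
    cv_scores = cross_validate_roster(X_train, y_train, roster, config)
    best_id = select_best(cv_scores, roster)
    spec = roster_by_id(roster, best_id)
    result, model = fit_and_validate(spec, X_train, y_train, X_val, y_val, config)
    rows = []
    for i in range(len(y_val)):
        row: dict[str, Any] = {
            "predicted": result.predicted[i],
            "real": int(y_val[i]),
        }
        for j, c in enumerate(result.classes):
            row[f"p_class_{c}"] = result.probabilities[i][j]
        for name in predictors:
            spec_v = schema[name]
            row[name] = spec_v.display_value(val.values.iloc[i][name])
        rows.append(row)
    return EvaluationReport(
        config=config,
        predictors=list(predictors),
        cv_scores=cv_scores,
        best_id=best_id,
        selection_score=float(np.mean(cv_scores[best_id])),
        result=result,
        per_sample=pd.DataFrame(rows),
        plan=plan,
        model=model,
        schema=schema,
        train_matrix=X_train,
        y_train=y_train,
    )


# ---------------------------------------------------------------------------
# Model bundle persistence
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    """Everything needed to score and explain new samples."""

    schema: DatasetSchema
    plan: TransformPlan
    config: TaskConfig
    classifier: dict
    model: Any
    classes: list[int]
    background: np.ndarray  # encoded training rows (capped) for explanations

    @property
    def predictors(self) -> list[str]:
        return list(self.plan.predictors)

    def design_matrix(self, table: ClinicalTable) -> pd.DataFrame:
        missing = [p for p in self.predictors if p not in table.columns]
        if missing:
            raise EvaluationError(f"input lacks required predictor(s): {missing}")
        return apply_transform(self.plan, table, self.schema)

    def predict_proba(self, table: ClinicalTable) -> np.ndarray:
        """Per-class probabilities, columns ordered like ``self.classes``."""
        X = np.asarray(self.design_matrix(table), dtype=float)
        return self.model.predict_proba(X)  # fitted on encoded 0..K-1 labels

    def predict(self, table: ClinicalTable) -> np.ndarray:
        proba = self.predict_proba(table)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]

    def save(self, path) -> None:
        meta = {
            "format_version": "1",
            "roster_version": ROSTER_VERSION,
            "schema": schema_to_dict(self.schema),
            "plan": self.plan.to_dict(),
            "config": self.config.to_dict(),
            "classifier": self.classifier,
            "classes": self.classes,
        }
        buf = io.BytesIO()
        joblib.dump({"model": self.model, "background": self.background}, buf)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta, sort_keys=True, indent=1))
            zf.writestr("model.joblib", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            blob = joblib.load(io.BytesIO(zf.read("model.joblib")))
        return cls(
            schema=schema_from_dict(meta["schema"]),
            plan=TransformPlan.from_dict(meta["plan"]),
            config=TaskConfig.from_dict(meta["config"]),
            classifier=meta["classifier"],
            model=blob["model"],
            classes=[int(c) for c in meta["classes"]],
            background=np.asarray(blob["background"], dtype=float),
        )


def bundle_from_report(report: EvaluationReport, roster: Sequence[ClassifierSpec] | None = None) -> ModelBundle:
    roster = list(roster) if roster is not None else default_roster(report.config.seed)
    spec = roster_by_id(roster, report.best_id)
    background = np.asarray(report.train_matrix, dtype=float)[:BACKGROUND_LIMIT]
    return ModelBundle(
        schema=report.schema,
        plan=report.plan,
        config=report.config,
        classifier=spec.to_dict(),
        model=report.model,
        classes=report.result.classes,
        background=background,
    )


def persist_model(report: EvaluationReport, path, roster: Sequence[ClassifierSpec] | None = None) -> ModelBundle:
    bundle = bundle_from_report(report, roster)
    bundle.save(path)
    return bundle


def load_model(path) -> ModelBundle:
    return ModelBundle.load(path)
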