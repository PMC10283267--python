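"""Wrapper feature selection.

Two strategies over subsets of candidate predictors, both scoring each
subset by the cross-validated fold-mean metric of its best roster
classifier:

* **Exhaustive** (N <= 13): every subset of size >= 2, enumerated from
  the full set downward; ``c = 2**N - N - 1`` evaluations.
* **Sequential backward (SBS) variant** (N > 13): start from the full
  set T of size T=N; at each iteration evaluate all size-(T-k) subsets
  of T, replace T by the best subset of the iteration, and repeat until
  T - k < 2.  The evaluation budget is fully determined by (N, k):
  ``1 + sum over the T-trajectory of C(T, k)``.

Subset scores are comparable because every subset is evaluated against
the same stratified train/validation split and the same fold assignment
(both fixed by the task seed), with the design matrix built once over
all candidate features and column-sliced per subset.
"""

from __future__ import annotations

import io
import json
import csv as _csv
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

from .evaluate import (
    ClassifierSpec,
    EvaluationReport,
    TaskConfig,
    cross_validate_roster,
    default_roster,
    evaluate_task,
    prepare_task,
    select_best,
)
from .schema import ClinicalTable, DatasetSchema

#: Largest candidate-set size for which all combinations are tested.
EXHAUSTIVE_MAX = 13
#: Default number of features removed per SBS iteration.
DEFAULT_K = 2


class SearchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Combinatorics
# ---------------------------------------------------------------------------


def count_combinations(n_features: int) -> int:
    """Number of feature subsets of size >= 2: ``2**N - N - 1``."""
    if n_features < 2:
        raise SearchError("at least 2 candidate features are required")
    return 2**n_features - n_features - 1


def enumerate_subsets(features: Sequence[str]) -> Iterator[tuple[str, ...]]:
    """All subsets of size >= 2, full set first, sizes non-increasing."""
    features = tuple(features)
    if len(features) < 2:
        raise SearchError("at least 2 candidate features are required")
    for size in range(len(features), 1, -1):
        yield from combinations(features, size)


def count_sbs_evaluations(n_features: int, k: int) -> int:
    """Planned evaluation count of :func:`sbs_search`, independent of data:
    one full-set evaluation plus C(T, k) per iteration along the
    trajectory T = N, N-k, N-2k, ... while T - k >= 2."""
    _check_sbs_params(n_features, k)
    total = 1
    t = n_features
    while t - k >= 2:
        total += comb(t, k)
        t -= k
    return total


def _check_sbs_params(n_features: int, k: int) -> None:
    if k < 1:
        raise SearchError("removal parameter k must be at least 1")
    if k >= n_features:
        raise SearchError(f"k={k} must be smaller than the feature count N={n_features}")


# ---------------------------------------------------------------------------
# Search records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchRecord:
    subset: tuple[str, ...]
    best_classifier: str
    score: float
    cv_scores: dict[str, list[float]]

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "subset_size": len(self.subset),
            "best_classifier": self.best_classifier,
            "score": self.score,
            "cv_means": {k: float(np.mean(v)) for k, v in self.cv_scores.items()},
        }


@dataclass
class SearchReport:
    """Full trace of a feature-selection run."""

    algorithm: str  # "exhaustive" | "sbs"
    features: list[str]
    k: int | None
    config: TaskConfig
    records: list[SearchRecord]
    best: SearchRecord

    @property
    def evaluations_performed(self) -> int:
        return len(self.records)

    def running_best(self) -> list[float]:
        """Best score seen so far, per evaluation, in evaluation order."""
        out, cur = [], -np.inf
        for r in self.records:
            cur = max(cur, r.score)
            out.append(float(cur))
        return out

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "features": self.features,
            "k": self.k,
            "config": self.config.to_dict(),
            "evaluations_performed": self.evaluations_performed,
            "best": self.best.to_dict(),
            "trace": [r.to_dict() for r in self.records],
            "running_best": self.running_best(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def trace_csv(self) -> str:
        """Score-vs-combination series: one row per evaluated subset."""
        out = io.StringIO()
        writer = _csv.writer(out, lineterminator="\n")
        writer.writerow(["index", "subset_size", "score", "best_classifier", "subset"])
        for i, r in enumerate(self.records):
            writer.writerow([i, len(r.subset), repr(r.score), r.best_classifier, ";".join(r.subset)])
        return out.getvalue()


def _better(candidate: SearchRecord, incumbent: SearchRecord | None) -> bool:
    """Tie rules: higher score; then smaller subset; then earlier order."""
    if incumbent is None:
        return True
    if candidate.score != incumbent.score:
        return candidate.score > incumbent.score
    return len(candidate.subset) < len(incumbent.subset)


# ---------------------------------------------------------------------------
# Subset evaluator
# ---------------------------------------------------------------------------


def make_subset_evaluator(
    table: ClinicalTable,
    schema: DatasetSchema,
    features: Sequence[str],
    config: TaskConfig,
    roster: Sequence[ClassifierSpec] | None = None,
) -> Callable[[tuple[str, ...]], SearchRecord]:
    """Build the shared-split subset scorer.

    Fits the transform plan and encodes the training partition once over
    all candidate features; each subset evaluation slices the relevant
    encoded columns and cross-validates the roster on them.
    """
    roster = list(roster) if roster is not None else default_roster(config.seed)
    plan, X_train, y_train, _, _, _, _ = prepare_task(table, schema, features, config)
    columns_of = {
        f: [c for c in plan.encoded_columns if plan.column_map[c] == f] for f in features
    }

    def evaluate(subset: tuple[str, ...]) -> SearchRecord:
        cols = [c for f in subset for c in columns_of[f]]
        cv_scores = cross_validate_roster(X_train[cols], y_train, roster, config)
        best_id = select_best(cv_scores, roster)
        return SearchRecord(
            subset=tuple(subset),
            best_classifier=best_id,
            score=float(np.mean(cv_scores[best_id])),
            cv_scores=cv_scores,
        )

    return evaluate


# ---------------------------------------------------------------------------
# Search strategies
# ---------------------------------------------------------------------------


def full_search(
    table: ClinicalTable,
    schema: DatasetSchema,
    features: Sequence[str],
    config: TaskConfig,
    roster: Sequence[ClassifierSpec] | None = None,
    progress: Callable[[int, int, SearchRecord], None] | None = None,
    evaluator: Callable[[tuple[str, ...]], SearchRecord] | None = None,
) -> SearchReport:
    """Exhaustive wrapper search over every subset of size >= 2 (N <= 13)."""
    features = list(features)
    n = len(features)
    if not 2 <= n <= EXHAUSTIVE_MAX:
        raise SearchError(f"exhaustive search requires 2 <= N <= {EXHAUSTIVE_MAX}, got N={n}")
    if evaluator is None:
        evaluator = make_subset_evaluator(table, schema, features, config, roster)
    total = count_combinations(n)
    records: list[SearchRecord] = []
    best: SearchRecord | None = None
    for i, subset in enumerate(enumerate_subsets(features)):
        record = evaluator(subset)
        records.append(record)
        if _better(record, best):
            best = record
        if progress is not None:
            progress(i + 1, total, record)
    assert best is not None and len(records) == total
    return SearchReport("exhaustive", features, None, config, records, best)


def sbs_search(
    table: ClinicalTable,
    schema: DatasetSchema,
    features: Sequence[str],
    config: TaskConfig,
    k: int = DEFAULT_K,
    roster: Sequence[ClassifierSpec] | None = None,
    progress: Callable[[int, int, SearchRecord], None] | None = None,
    evaluator: Callable[[tuple[str, ...]], SearchRecord] | None = None,
    checkpoint_path: str | Path | None = None,
) -> SearchReport:
    """Sequential-backward wrapper search removing k features per iteration.

    The full candidate set is evaluated once at initialization; each
    iteration then evaluates all size-(T-k) subsets of the current test
    set and keeps the iteration's best subset as the new test set.  The
    global best is taken over the entire trace.  When ``checkpoint_path``
    is given the trace is rewritten there after every iteration.
    """
    features = list(features)
    _check_sbs_params(len(features), k)
    if evaluator is None:
        evaluator = make_subset_evaluator(table, schema, features, config, roster)
    total = count_sbs_evaluations(len(features), k)
    records: list[SearchRecord] = []
    best: SearchRecord | None = None

    def note(record: SearchRecord) -> SearchRecord:
        nonlocal best
        records.append(record)
        if _better(record, best):
            best = record
        if progress is not None:
            progress(len(records), total, record)
        return record

    def checkpoint() -> None:
        if checkpoint_path is not None:
            partial = SearchReport("sbs", features, k, config, records, best)
            Path(checkpoint_path).write_text(partial.to_json())

    note(evaluator(tuple(features)))
    checkpoint()
    current = tuple(features)
    while len(current) - k >= 2:
        iteration_best: SearchRecord | None = None
        for subset in combinations(current, len(current) - k):
            record = note(evaluator(subset))
            if _better(record, iteration_best):
                iteration_best = record
        assert iteration_best is not None
        current = iteration_best.subset
        checkpoint()
    assert best is not None and len(records) == total
    return SearchReport("sbs", features, k, config, records, best)


def select_features(
    table: ClinicalTable,
    schema: DatasetSchema,
    features: Sequence[str],
    config: TaskConfig,
    k: int = DEFAULT_K,
    roster: Sequence[ClassifierSpec] | None = None,
    force_exhaustive: bool = False,
    progress: Callable[[int, int, SearchRecord], None] | None = None,
    checkpoint_path: str | Path | None = None,
) -> SearchReport:
    """Dispatch: exhaustive for N <= 13 (or when forced), SBS above."""
    n = len(features)
    if n <= EXHAUSTIVE_MAX or force_exhaustive:
        return full_search(table, schema, features, config, roster, progress)
    return sbs_search(table, schema, features, config, k, roster, progress, checkpoint_path=checkpoint_path)


def evaluate_best_subset(
    table: ClinicalTable,
    schema: DatasetSchema,
    report: SearchReport,
    roster: Sequence[ClassifierSpec] | None = None,
) -> EvaluationReport:
    """Run the full evaluation workflow (refit + held-out validation +
    bundle-ready model) on the winning subset of a search."""
    return evaluate_task(table, schema, list(report.best.subset), report.config, roster)
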