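"""Shapley-additive explanations and report assembly.

Both explanation paths compute *interventional* Shapley values of the
model's class-of-interest probability: the payoff of a feature coalition
S for a sample x is the model output averaged over background rows b
with the features in S taken from x and the rest from b.  The base
value is the mean model output over the background, and for every
sample ``base + sum(contributions) == model_output`` exactly (up to
floating-point error).

* ``exact_enumeration`` evaluates all ``2**m`` coalitions of the ``m``
  encoded columns — exact for any model, refused above a configurable
  feature cap rather than silently approximated.
* ``tree_exact`` decomposes a fitted decision tree (or forest, by
  linearity of the forest's probability average) into per-leaf games.
  For one sample/background pair, a leaf is reached under coalition S
  iff S contains every path feature satisfied only by the sample (set A)
  and no path feature satisfied only by the background (set B); the
  Shapley value of that unanimity-with-veto indicator game is
  ``(|A|-1)! |B|! / (|A|+|B|)!`` for members of A and the negated
  mirror for members of B.  Summing over leaves and averaging over the
  background gives the exact interventional values at polynomial cost.

One-hot child columns are aggregated into their parent variables for
all global displays; additivity makes the aggregation exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import factorial
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, export_graphviz

from .evaluate import ModelBundle
from .schema import ClinicalTable, DatasetSchema, VariableKind

#: Refuse exact coalition enumeration above this many encoded columns.
MAX_EXACT_FEATURES = 16


class ExplainError(ValueError):
    pass


@dataclass(frozen=True)
class ExplainConfig:
    explainer: str = "auto"  # {"auto", "tree_exact", "exact_enumeration"}
    background_limit: int = 1000
    output_space: str = "probability"
    max_exact_features: int = MAX_EXACT_FEATURES

    def __post_init__(self) -> None:
        if self.explainer not in ("auto", "tree_exact", "exact_enumeration"):
            raise ExplainError(f"unknown explainer {self.explainer!r}")
        if self.background_limit < 1:
            raise ExplainError("background_limit must be >= 1")
        if self.output_space != "probability":
            raise ExplainError("only probability-space explanations are supported")


# ---------------------------------------------------------------------------
# Exact coalition enumeration (model-agnostic)
# ---------------------------------------------------------------------------


def exact_enumeration_shap(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    max_features: int = MAX_EXACT_FEATURES,
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values by enumerating all coalitions.

    Returns (values of shape (n, m), base_value).
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, m = X.shape
    if m > max_features:
        raise ExplainError(
            f"{m} encoded features exceed the exact-enumeration cap of {max_features}; "
            "use the tree explainer or reduce the feature set"
        )
    n_coalitions = 1 << m
    # coalition masks: row c has bit j set iff feature j comes from the sample
    masks = (np.arange(n_coalitions)[:, None] >> np.arange(m)) & 1  # (C, m)
    sizes = masks.sum(axis=1)
    # Shapley weight of the marginal contribution added to a coalition of size s
    weights = np.array([factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)])
    base_value = float(np.mean(predict(background)))
    values = np.zeros((n, m))
    B = len(background)
    chunk = max(1, 2_000_000 // max(B * m, 1))  # bound peak memory
    for i in range(n):
        v = np.empty(n_coalitions)
        for start in range(0, n_coalitions, chunk):
            part = masks[start : start + chunk].astype(bool)
            mixed = np.where(part[:, None, :], X[i], background[None, :, :])
            v[start : start + chunk] = (
                predict(mixed.reshape(len(part) * B, m)).reshape(len(part), B).mean(axis=1)
            )
        for j in range(m):
            without = np.flatnonzero((masks[:, j] == 0))
            with_j = without | (1 << j)
            values[i, j] = float(np.sum(weights[sizes[without]] * (v[with_j] - v[without])))
    return values, base_value


# ---------------------------------------------------------------------------
# Exact tree-path explainer
# ---------------------------------------------------------------------------


def _tree_leaves(tree) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Flatten a fitted sklearn tree into per-leaf path constraints.

    Each entry is (path feature indices, lower bounds, upper bounds,
    class-probability vector); a value v passes constraint j iff
    ``lo[j] < v <= hi[j]`` (sklearn sends v <= threshold left).
    """
    t = tree.tree_
    leaves = []

    def walk(node: int, bounds: dict[int, tuple[float, float]]) -> None:
        if t.children_left[node] == -1:
            counts = np.asarray(t.value[node][0], dtype=float)
            prob = counts / counts.sum()
            feats = np.array(sorted(bounds), dtype=int)
            lo = np.array([bounds[f][0] for f in feats])
            hi = np.array([bounds[f][1] for f in feats])
            leaves.append((feats, lo, hi, prob))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        walk(t.children_left[node], {**bounds, f: (lo, min(hi, thr))})
        walk(t.children_right[node], {**bounds, f: (max(lo, thr), hi)})

    walk(0, {})
    return leaves


def _indicator_game_weights(a: int, b: int) -> tuple[float, float]:
    """Shapley value magnitudes of the game v(S)=[A<=S and S&B=0] for
    members of A (positive) and B (negative)."""
    pos = factorial(a - 1) * factorial(b) / factorial(a + b) if a else 0.0
    neg = factorial(a) * factorial(b - 1) / factorial(a + b) if b else 0.0
    return pos, neg


def tree_exact_shap(
    model,
    class_index: int,
    X: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for a decision tree or a
    random forest (averaged over member trees)."""
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if isinstance(model, DecisionTreeClassifier):
        trees = [model]
    elif isinstance(model, RandomForestClassifier):
        trees = list(model.estimators_)
    else:
        raise ExplainError(f"tree explainer does not support {type(model).__name__}")
    n, m = X.shape
    values = np.zeros((n, m))
    base = 0.0
    for tree in trees:
        v, b = _tree_exact_single(tree, class_index, X, background)
        values += v
        base += b
    return values / len(trees), base / len(trees)


def _tree_exact_single(tree, class_index: int, X: np.ndarray, background: np.ndarray):
    n, m = X.shape
    nb = len(background)
    values = np.zeros((n, m))
    base = float(tree.predict_proba(background)[:, class_index].mean())
    for feats, lo, hi, prob in _tree_leaves(tree):
        leaf_val = float(prob[class_index])
        if leaf_val == 0.0 or len(feats) == 0:
            continue
        d = len(feats)
        bits = 1 << np.arange(d)
        x_pass = (lo[None, :] < X[:, feats]) & (X[:, feats] <= hi[None, :])
        b_pass = (lo[None, :] < background[:, feats]) & (background[:, feats] <= hi[None, :])
        x_pat = (x_pass * bits).sum(axis=1)
        b_pat, b_counts = np.unique((b_pass * bits).sum(axis=1), return_counts=True)
        full = (1 << d) - 1
        for xp in np.unique(x_pat):
            xp = int(xp)
            rows = np.flatnonzero(x_pat == xp)
            for bp, cnt in zip(b_pat, b_counts):
                bp = int(bp)
                if (~xp) & (~bp) & full:
                    continue  # some path feature satisfied by neither source
                a_mask = xp & ~bp & full
                b_mask = bp & ~xp & full
                a = int(bin(a_mask).count("1"))
                b = int(bin(b_mask).count("1"))
                if a == 0 and b == 0:
                    continue  # leaf reached regardless of the coalition
                pos, neg = _indicator_game_weights(a, b)
                frac = cnt / nb
                if a:
                    cols = feats[np.flatnonzero((a_mask >> np.arange(d)) & 1)]
                    values[np.ix_(rows, cols)] += leaf_val * pos * frac
                if b:
                    cols = feats[np.flatnonzero((b_mask >> np.arange(d)) & 1)]
                    values[np.ix_(rows, cols)] -= leaf_val * neg * frac
    return values, base


# ---------------------------------------------------------------------------
# Explanation bundle
# ---------------------------------------------------------------------------


@dataclass
class ExplanationBundle:
    """Per-sample, per-feature additive contributions plus everything
    needed to aggregate, display and redraw them."""

    values: np.ndarray  # (n, m) encoded-column contributions
    base_value: float
    data: np.ndarray  # (n, m) encoded design-matrix values
    feature_names: list[str]  # encoded columns
    column_map: dict[str, str]  # encoded column -> parent variable
    parent_names: list[str]  # predictor order
    class_label: int
    explainer: str
    schema: DatasetSchema
    table_values: pd.DataFrame | None = None  # raw predictor cells, row-aligned

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def model_output(self) -> np.ndarray:
        """base + sum of contributions, per sample (equals the model's
        class probability by the additivity invariant)."""
        return self.base_value + self.values.sum(axis=1)

    def parent_values(self) -> pd.DataFrame:
        """Contributions aggregated from one-hot children to parents."""
        cols = {p: np.zeros(self.n_samples) for p in self.parent_names}
        for j, name in enumerate(self.feature_names):
            cols[self.column_map[name]] += self.values[:, j]
        return pd.DataFrame(cols, columns=self.parent_names)

    def parent_numeric(self) -> pd.DataFrame:
        """Numeric per-parent display values: scalar kinds as-is,
        tooth-lists as set cardinality."""
        if self.table_values is None:
            raise ExplainError("this bundle carries no raw table values")
        out = {}
        for p in self.parent_names:
            spec = self.schema[p]
            cells = self.table_values[p]
            if spec.kind is VariableKind.TOOTHLIST:
                out[p] = np.array([len(c) for c in cells], dtype=float)
            else:
                out[p] = np.array([float(v) for v in cells])
        return pd.DataFrame(out, columns=self.parent_names, index=self.table_values.index)

    def to_dict(self) -> dict:
        return {
            "explainer": self.explainer,
            "class_label": self.class_label,
            "base_value": self.base_value,
            "feature_names": self.feature_names,
            "parent_names": self.parent_names,
            "values": self.values.tolist(),
            "parent_values": self.parent_values().to_numpy().tolist(),
            "data": self.data.tolist(),
        }


def compute_shap(
    bundle: ModelBundle,
    table: ClinicalTable | pd.DataFrame,
    config: ExplainConfig = ExplainConfig(),
) -> ExplanationBundle:
    """Explain a model bundle's predictions on a table (or a precomputed
    design matrix).  Tree-based fitted models take the exact tree path;
    anything else takes exact coalition enumeration."""
    if isinstance(table, ClinicalTable):
        X_df = bundle.design_matrix(table)
        raw = table.values.reset_index(drop=True)  # all columns: grouping vars too
    else:
        X_df = table
        raw = None
    X = np.asarray(X_df, dtype=float)
    background = np.asarray(bundle.background, dtype=float)[: config.background_limit]
    classes = list(bundle.classes)
    coi = bundle.config.class_of_interest
    class_label = int(coi) if coi is not None else classes[-1]
    class_index = classes.index(class_label)

    is_tree = isinstance(bundle.model, (DecisionTreeClassifier, RandomForestClassifier))
    explainer = config.explainer
    if explainer == "auto":
        explainer = "tree_exact" if is_tree else "exact_enumeration"
    if explainer == "tree_exact":
        if not is_tree:
            raise ExplainError("tree_exact requires a decision-tree or random-forest model")
        values, base = tree_exact_shap(bundle.model, class_index, X, background)
    else:
        predict = lambda Z: bundle.model.predict_proba(Z)[:, class_index]
        values, base = exact_enumeration_shap(predict, X, background, config.max_exact_features)
    plan = bundle.plan
    return ExplanationBundle(
        values=values,
        base_value=base,
        data=X,
        feature_names=list(plan.encoded_columns),
        column_map=dict(plan.column_map),
        parent_names=list(plan.predictors),
        class_label=class_label,
        explainer=explainer,
        schema=bundle.schema,
        table_values=raw,
    )


# ---------------------------------------------------------------------------
# Global importance, dependence, waterfalls
# ---------------------------------------------------------------------------


def global_importance(
    bundle: ExplanationBundle,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Features ranked by mean |contribution| (parent-aggregated).

    With ``group_by`` (a binary predictor), one importance column per
    group in addition to the overall ranking order.
    """
    parent = bundle.parent_values()
    overall = parent.abs().mean(axis=0)
    order = overall.sort_values(ascending=False, kind="stable").index
    out = pd.DataFrame({"importance": overall[order]})
    if group_by is not None:
        spec = bundle.schema[group_by]
        if spec.kind is not VariableKind.BINARY:
            raise ExplainError(f"group_by variable {group_by!r} must be binary")
        if bundle.table_values is None:
            raise ExplainError("grouped importance needs raw table values")
        groups = np.array([int(v) for v in bundle.table_values[group_by]])
        for g in (0, 1):
            sel = groups == g
            label = spec.display_value(g)
            col = parent[sel].abs().mean(axis=0) if sel.any() else pd.Series(0.0, index=parent.columns)
            out[f"importance[{label}]"] = col[order]
    return out


def strongest_interaction_partner(bundle: ExplanationBundle, feature: str, n_bins: int = 10) -> str:
    """Heuristic partner pick: the candidate whose values best explain
    the spread of ``feature``'s contributions within bins of the
    feature's own value (size-weighted squared correlation)."""
    phi = bundle.parent_values()[feature].to_numpy()
    numeric = bundle.parent_numeric()
    x = numeric[feature].to_numpy()
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, max(len(edges) - 2, 0))
    best_partner, best_score = None, -1.0
    for partner in bundle.parent_names:
        if partner == feature:
            continue
        p = numeric[partner].to_numpy()
        score, weight = 0.0, 0
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < 3 or np.std(p[sel]) == 0 or np.std(phi[sel]) == 0:
                continue
            r = np.corrcoef(p[sel], phi[sel])[0, 1]
            score += sel.sum() * r * r
            weight += sel.sum()
        score = score / weight if weight else 0.0
        if score > best_score:
            best_partner, best_score = partner, score
    if best_partner is None:
        raise ExplainError("no candidate partner available")
    return best_partner


def dependence_pairs(
    bundle: ExplanationBundle,
    feature: str,
    partner: str | None = None,
) -> dict:
    """Data behind a dependence plot: feature values, the feature's
    contributions, and the (auto-selected or overridden) partner's
    values, plus histogram bins of the feature values."""
    if feature not in bundle.parent_names:
        raise ExplainError(f"unknown feature {feature!r}")
    if partner is None:
        partner = strongest_interaction_partner(bundle, feature)
    elif partner not in bundle.parent_names:
        raise ExplainError(f"unknown partner {partner!r}")
    numeric = bundle.parent_numeric()
    counts, edges = np.histogram(numeric[feature].to_numpy(), bins=10)
    return {
        "feature": feature,
        "partner": partner,
        "feature_values": numeric[feature].to_numpy().tolist(),
        "contributions": bundle.parent_values()[feature].to_numpy().tolist(),
        "partner_values": numeric[partner].to_numpy().tolist(),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }


def waterfall(bundle: ExplanationBundle, sample_index: int) -> dict:
    """Ordered per-feature contributions for one sample, largest
    magnitude first; display values use the schema legends."""
    if not 0 <= sample_index < bundle.n_samples:
        raise ExplainError(f"sample index {sample_index} out of range")
    parent = bundle.parent_values().iloc[sample_index]
    order = parent.abs().sort_values(ascending=False, kind="stable").index
    entries = []
    for name in order:
        display = None
        if bundle.table_values is not None:
            display = bundle.schema[name].display_value(bundle.table_values[name].iloc[sample_index])
        entries.append({"feature": name, "contribution": float(parent[name]), "display_value": display})
    return {
        "sample_index": sample_index,
        "base_value": bundle.base_value,
        "prediction": float(bundle.model_output()[sample_index]),
        "class_label": bundle.class_label,
        "contributions": entries,
    }


# ---------------------------------------------------------------------------
# Decision-tree export and relevance clustering
# ---------------------------------------------------------------------------


def export_tree(bundle: ModelBundle) -> dict:
    """DOT export of the fitted best model when it is a decision tree;
    otherwise an explicit non-tree marker (never an error)."""
    model = bundle.model
    if not isinstance(model, DecisionTreeClassifier):
        return {"is_tree": False}
    dot = export_graphviz(
        model,
        feature_names=list(bundle.plan.encoded_columns),
        class_names=[str(c) for c in bundle.classes],
        filled=False,
        impurity=False,
    )
    return {
        "is_tree": True,
        "dot": dot,
        "n_nodes": int(model.tree_.node_count),
        "n_leaves": int(model.tree_.n_leaves),
        "depth": int(model.tree_.max_depth),
    }


def relevance_clustering(bundle: ExplanationBundle, n_clusters: int = 2) -> dict:
    """Average-linkage hierarchical clustering of samples by their
    parent-level contribution vectors (Euclidean distance)."""
    if bundle.n_samples < 2:
        raise ExplainError("clustering needs at least 2 samples")
    parent = bundle.parent_values().to_numpy()
    linkage = hierarchy.linkage(parent, method="average", metric="euclidean")
    leaf_order = hierarchy.leaves_list(linkage)
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return {
        "linkage": linkage.tolist(),
        "leaf_order": leaf_order.tolist(),
        "labels": labels.tolist(),
        "n_clusters": int(n_clusters),
    }


# ---------------------------------------------------------------------------
# Report document
# ---------------------------------------------------------------------------

REPORT_REQUIRED_KEYS = {
    "report_version": str,
    "task": dict,
    "roster_metrics": dict,
    "best_model": dict,
    "explanations": dict,
}


class ReportSchemaError(ValueError):
    pass


def validate_report(document: Mapping[str, Any]) -> None:
    """Structural check of a report document; raises on violations."""
    for key, kind in REPORT_REQUIRED_KEYS.items():
        if key not in document:
            raise ReportSchemaError(f"report lacks required section {key!r}")
        if not isinstance(document[key], kind):
            raise ReportSchemaError(f"report section {key!r} must be a {kind.__name__}")
    expl = document["explanations"]
    for key in ("base_value", "parent_names", "parent_values", "global_importance"):
        if key not in expl:
            raise ReportSchemaError(f"explanations section lacks {key!r}")
    if "search" in document and document["search"] is not None:
        trace = document["search"].get("trace", [])
        if document["search"].get("evaluations_performed") != len(trace):
            raise ReportSchemaError("search trace length must equal evaluations_performed")


def build_report(
    evaluation,
    explanation: ExplanationBundle,
    search=None,
    model_bundle: ModelBundle | None = None,
) -> dict:
    """Assemble the full report document.

    Carries the data behind every figure (trace series, importance
    table, dependence triples, per-sample waterfalls), not just images.
    """
    importance = global_importance(explanation)
    top_feature = str(importance.index[0]) if len(importance) else None
    dependence = None
    if top_feature is not None and len(explanation.parent_names) > 1:
        dependence = dependence_pairs(explanation, top_feature)
    document: dict[str, Any] = {
        "report_version": "1",
        "task": evaluation.config.to_dict(),
        "roster_metrics": {
            "cv_scores": evaluation.cv_scores,
            "cv_means": {k: float(np.mean(v)) for k, v in evaluation.cv_scores.items()},
        },
        "best_model": {
            "classifier": evaluation.best_id,
            "predictors": evaluation.predictors,
            "selection_score": evaluation.selection_score,
            "validation": evaluation.result.to_dict(),
            "per_sample": evaluation.per_sample.to_dict(orient="records"),
        },
        "explanations": {
            "explainer": explanation.explainer,
            "class_label": explanation.class_label,
            "base_value": explanation.base_value,
            "parent_names": explanation.parent_names,
            "parent_values": explanation.parent_values().to_numpy().tolist(),
            "global_importance": {str(k): float(v) for k, v in importance["importance"].items()},
            "dependence": dependence,
            "waterfalls": [waterfall(explanation, i) for i in range(explanation.n_samples)],
            "clustering": relevance_clustering(explanation) if explanation.n_samples >= 2 else None,
        },
        "search": None,
        "decision_tree": export_tree(model_bundle) if model_bundle is not None else {"is_tree": False},
    }
    if search is not None:
        document["search"] = {
            "algorithm": search.algorithm,
            "k": search.k,
            "evaluations_performed": search.evaluations_performed,
            "best_subset": list(search.best.subset),
            "trace": [r.to_dict() for r in search.records],
            "running_best": search.running_best(),
        }
    validate_report(document)
    return document
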