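"""Shapley explanations: additivity, oracle equivalence, reports."""

from itertools import chain, combinations
from math import factorial

import numpy as np
import pytest

from clinselect import (
    ExplainConfig,
    TaskConfig,
    bundle_from_report,
    build_report,
    compute_shap,
    dependence_pairs,
    evaluate_task,
    export_tree,
    global_importance,
    relevance_clustering,
    validate_report,
    waterfall,
)
from clinselect.explain import (
    ExplainError,
    ReportSchemaError,
    exact_enumeration_shap,
    tree_exact_shap,
)
from clinselect.simulate import SyntheticSpec, generate_case_study_like


def brute_force_shap(predict, x, background):
    """Independent oracle: the permutation-weight Shapley formula with the
    interventional value function, enumerating every coalition."""
    m = len(x)
    background = np.asarray(background, float)

    def value(S):
        z = np.array(background, copy=True)
        if S:
            z[:, list(S)] = x[list(S)]
        return float(predict(z).mean())

    phi = np.zeros(m)
    for i in range(m):
        others = [j for j in range(m) if j != i]
        for S in chain.from_iterable(combinations(others, r) for r in range(m)):
            w = factorial(len(S)) * factorial(m - len(S) - 1) / factorial(m)
            phi[i] += w * (value(tuple(S) + (i,)) - value(S))
    return phi


@pytest.fixture(scope="module")
def fitted():
    """A decision tree and a logistic model fitted on the same small
    mixed dataset, bundled for explanation."""
    spec = SyntheticSpec(
        seed=13, n_binary=3, n_categorical=1, n_integer=2, n_continuous=1, n_toothlist=1,
        planted_effects={"Num1": 2.0, "Bin2": 1.5},
    )
    table, schema = generate_case_study_like(spec)
    config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=13)
    preds = ["Bin2", "Bin3", "Num1", "Num2", "Cont1"]
    from clinselect import default_roster

    tree_roster = [s for s in default_roster(13) if s.id == "decision_tree"]
    logit_roster = [s for s in default_roster(13) if s.id == "logistic_regression"]
    tree_rep = evaluate_task(table, schema, preds, config, tree_roster)
    logit_rep = evaluate_task(table, schema, preds, config, logit_roster)
    return {
        "table": table,
        "schema": schema,
        "tree": bundle_from_report(tree_rep, tree_roster),
        "logit": bundle_from_report(logit_rep, logit_roster),
        "tree_report": tree_rep,
    }


class TestAdditivity:
    @pytest.mark.parametrize("explainer", ["tree_exact", "exact_enumeration"])
    def test_base_plus_contributions_equals_output(self, fitted, explainer):
        bundle = fitted["tree"]
        sub = fitted["table"].take_rows(fitted["table"].values.index[:25])
        expl = compute_shap(bundle, sub, ExplainConfig(explainer=explainer, background_limit=60))
        X = np.asarray(bundle.design_matrix(sub), float)
        f = bundle.model.predict_proba(X)[:, 1]
        assert np.abs(expl.model_output() - f).max() < 1e-6

    def test_non_tree_model_enumeration_additivity(self, fitted):
        bundle = fitted["logit"]
        sub = fitted["table"].take_rows(fitted["table"].values.index[:10])
        expl = compute_shap(bundle, sub, ExplainConfig(background_limit=40))
        X = np.asarray(bundle.design_matrix(sub), float)
        f = bundle.model.predict_proba(X)[:, 1]
        assert expl.explainer == "exact_enumeration"
        assert np.abs(expl.model_output() - f).max() < 1e-6


class TestOracleEquivalence:
    def test_enumeration_matches_brute_force(self, fitted):
        bundle = fitted["logit"]
        sub = fitted["table"].take_rows(fitted["table"].values.index[:3])
        expl = compute_shap(bundle, sub, ExplainConfig(background_limit=30))
        X = np.asarray(bundle.design_matrix(sub), float)
        bg = bundle.background[:30]
        predict = lambda Z: bundle.model.predict_proba(Z)[:, 1]
        for i in range(len(X)):
            oracle = brute_force_shap(predict, X[i], bg)
            assert np.abs(expl.values[i] - oracle).max() < 1e-6

    def test_tree_path_matches_brute_force(self, fitted):
        bundle = fitted["tree"]
        sub = fitted["table"].take_rows(fitted["table"].values.index[:3])
        expl = compute_shap(bundle, sub, ExplainConfig(explainer="tree_exact", background_limit=30))
        X = np.asarray(bundle.design_matrix(sub), float)
        bg = bundle.background[:30]
        predict = lambda Z: bundle.model.predict_proba(Z)[:, 1]
        for i in range(len(X)):
            oracle = brute_force_shap(predict, X[i], bg)
            assert np.abs(expl.values[i] - oracle).max() < 1e-6

    def test_depth1_tree_on_two_binary_features(self):
        """Hand-checkable case: a stump on binary features."""
        from sklearn.tree import DecisionTreeClassifier

        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]])
        y = np.array([0, 0, 1, 1])
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        predict = lambda Z: stump.predict_proba(Z)[:, 1]
        values, base = tree_exact_shap(stump, 1, X, X)
        for i in range(4):
            oracle = brute_force_shap(predict, X[i], X)
            assert np.abs(values[i] - oracle).max() < 1e-9
        assert base == pytest.approx(predict(X).mean())

    def test_constant_model_all_zero(self):
        predict = lambda Z: np.full(len(Z), 0.37)
        X = np.random.default_rng(0).random((4, 3))
        values, base = exact_enumeration_shap(predict, X, X)
        assert np.abs(values).max() == 0.0
        assert base == pytest.approx(0.37)

    def test_feature_cap_is_an_explicit_error(self):
        X = np.zeros((2, 20))
        with pytest.raises(ExplainError, match="cap"):
            exact_enumeration_shap(lambda Z: np.zeros(len(Z)), X, X, max_features=16)


class TestAggregation:
    def test_parent_equals_sum_of_children(self, small_signal, roster2):
        table, schema, _ = small_signal
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=11)
        tree_roster = [s for s in __import__("clinselect").default_roster(11) if s.id == "decision_tree"]
        rep = evaluate_task(table, schema, ["Num1", "Cat1", "ListTeeth1"], config, tree_roster)
        bundle = bundle_from_report(rep, tree_roster)
        sub = table.take_rows(table.values.index[:20])
        expl = compute_shap(bundle, sub, ExplainConfig(background_limit=50))
        parent = expl.parent_values()
        for p in expl.parent_names:
            child_cols = [j for j, c in enumerate(expl.feature_names) if expl.column_map[c] == p]
            assert np.allclose(parent[p].to_numpy(), expl.values[:, child_cols].sum(axis=1))


class TestGlobalImportance:
    def test_ranked_descending_and_zero_feature_last(self, fitted):
        bundle = fitted["tree"]
        expl = compute_shap(bundle, fitted["table"], ExplainConfig(background_limit=60))
        imp = global_importance(expl)
        vals = imp["importance"].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()
        parent = expl.parent_values()
        zero_feats = [p for p in expl.parent_names if np.abs(parent[p]).max() == 0]
        for z in zero_feats:
            assert imp.index.get_loc(z) >= len(imp) - len(zero_feats)

    def test_grouped_importance_two_values_per_feature(self, fitted):
        bundle = fitted["tree"]
        expl = compute_shap(bundle, fitted["table"], ExplainConfig(background_limit=60))
        imp = global_importance(expl, group_by="Healthy")
        group_cols = [c for c in imp.columns if c.startswith("importance[")]
        assert len(group_cols) == 2
        overall = imp["importance"]
        lo = imp[group_cols].min(axis=1)
        hi = imp[group_cols].max(axis=1)
        # the unweighted group mean brackets sanity: overall between group extremes (loose)
        mid = imp[group_cols].mean(axis=1)
        assert ((mid >= lo - 1e-12) & (mid <= hi + 1e-12)).all()

    def test_group_by_must_be_binary(self, fitted):
        expl = compute_shap(fitted["tree"], fitted["table"], ExplainConfig(background_limit=40))
        with pytest.raises(ExplainError, match="binary"):
            global_importance(expl, group_by="Num1")


class TestDependence:
    def test_explicit_partner_respected(self, fitted):
        expl = compute_shap(fitted["tree"], fitted["table"], ExplainConfig(background_limit=40))
        out = dependence_pairs(expl, "Num1", partner="Cont1")
        assert out["partner"] == "Cont1"
        assert len(out["feature_values"]) == expl.n_samples

    def test_planted_interaction_partner_recovered_majority_of_seeds(self):
        """With a planted Num1 x Bin2 interaction the auto-selected
        partner of Num1 should be Bin2 in most replicates."""
        from clinselect import default_roster
        from clinselect.simulate import interaction_spec

        hits = 0
        seeds = range(10)
        for seed in seeds:
            table, schema = generate_case_study_like(interaction_spec(seed=seed))
            config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=seed)
            roster = [s for s in default_roster(seed) if s.id == "decision_tree"]
            rep = evaluate_task(table, schema, ["Num1", "Bin2", "Bin3", "Cont1"], config, roster)
            bundle = bundle_from_report(rep, roster)
            expl = compute_shap(bundle, table, ExplainConfig(background_limit=80))
            if dependence_pairs(expl, "Num1")["partner"] == "Bin2":
                hits += 1
        assert hits > len(seeds) / 2

    def test_unknown_feature_rejected(self, fitted):
        expl = compute_shap(fitted["tree"], fitted["table"], ExplainConfig(background_limit=40))
        with pytest.raises(ExplainError, match="unknown"):
            dependence_pairs(expl, "Nope")


class TestWaterfall:
    def test_sum_check_every_sample(self, fitted):
        expl = compute_shap(fitted["tree"], fitted["table"], ExplainConfig(background_limit=60))
        for i in range(0, expl.n_samples, 23):
            w = waterfall(expl, i)
            total = w["base_value"] + sum(e["contribution"] for e in w["contributions"])
            assert total == pytest.approx(w["prediction"], abs=1e-9)
            mags = [abs(e["contribution"]) for e in w["contributions"]]
            assert mags == sorted(mags, reverse=True)

    def test_index_out_of_range(self, fitted):
        expl = compute_shap(fitted["tree"], fitted["table"], ExplainConfig(background_limit=40))
        with pytest.raises(ExplainError, match="out of range"):
            waterfall(expl, 10_000)


class TestTreeExport:
    def test_fitted_tree_exports_dot(self, fitted):
        out = export_tree(fitted["tree"])
        assert out["is_tree"]
        assert out["dot"].startswith("digraph")
        assert out["n_leaves"] <= 2 ** out["depth"]
        assert "Num1" in out["dot"]  # encoded-column labels carry parent names

    def test_non_tree_model_marker_not_error(self, fitted):
        out = export_tree(fitted["logit"])
        assert out == {"is_tree": False}


class TestClustering:
    def test_identical_samples_cluster_together(self, fitted):
        expl = compute_shap(fitted["tree"], fitted["table"], ExplainConfig(background_limit=40))
        labels = relevance_clustering(expl, n_clusters=2)["labels"]
        parent = expl.parent_values().to_numpy()
        dup = np.flatnonzero((parent == parent[0]).all(axis=1))
        assert len({labels[i] for i in dup}) == 1

    def test_planted_subpopulations_recovered(self):
        """Two subgroups whose outcome depends on different features
        should separate in the 2-cluster cut of the explanation space."""
        from sklearn.tree import DecisionTreeClassifier
        from clinselect.evaluate import ModelBundle

        rng = np.random.default_rng(3)
        n = 200
        g = rng.integers(0, 2, n)
        x1, x2 = rng.random(n), rng.random(n)
        y = np.where(g == 0, (x1 > 0.5), (x2 > 0.5)).astype(int)
        X = np.c_[g, x1, x2]
        model = DecisionTreeClassifier(max_depth=4, random_state=0).fit(X, y)
        values, _ = tree_exact_shap(model, 1, X, X[:100])
        linkage_input = values
        from scipy.cluster import hierarchy

        links = hierarchy.linkage(linkage_input, method="average")
        labels = hierarchy.fcluster(links, t=2, criterion="maxclust")
        from sklearn.metrics import adjusted_rand_score

        # explanation vectors are dominated by the active feature per group
        assert adjusted_rand_score(g, labels) > 0.8 or adjusted_rand_score(y, labels) > 0.8


class TestReportDocument:
    def test_full_document_validates_and_round_trips(self, fitted, roster2):
        import json

        table, schema = fitted["table"], fitted["schema"]
        config = TaskConfig(target="SecondSedation", class_of_interest=1, seed=13)
        from clinselect import full_search, evaluate_best_subset

        sr = full_search(table, schema, ["Bin2", "Num1", "Cont1"], config, roster=roster2)
        ev = evaluate_best_subset(table, schema, sr, roster2)
        bundle = bundle_from_report(ev, roster2)
        expl = compute_shap(bundle, table, ExplainConfig(background_limit=40))
        doc = build_report(ev, expl, search=sr, model_bundle=bundle)
        validate_report(doc)
        again = json.loads(json.dumps(doc))
        validate_report(again)
        assert len(again["search"]["trace"]) == sr.evaluations_performed == 4

    def test_missing_section_rejected(self):
        with pytest.raises(ReportSchemaError, match="roster_metrics"):
            validate_report({"report_version": "1", "task": {}, "best_model": {}, "explanations": {}})
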