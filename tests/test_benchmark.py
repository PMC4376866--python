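"""Benchmark set construction, screening, identity exclusion, evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pocketpath.benchmark import (
    build_negative_set,
    build_positive_set,
    evaluate,
    exclude_identity_links,
    screen_negatives,
)


class TestPositiveSet:
    def test_dedup(self):
        records = [("d1", "t1", "e1"), ("d1", "t1", "e2"), ("d2", "t1", "e3")]
        assert build_positive_set(records) == [("d1", "t1"), ("d2", "t1")]

    def test_empty_whitelist(self):
        assert build_positive_set([("d1", "t1", "e")], drug_whitelist=[]) == []

    def test_hand_counted_fixture(self):
        rng = np.random.default_rng(0)
        base = [("d1", "t1"), ("d1", "t2"), ("d2", "t1"), ("d2", "t3"),
                ("d3", "t1"), ("d3", "t2"), ("d3", "t3")]
        records = [(d, t, f"e{i}") for i, (d, t) in
                   enumerate(base + [base[0], base[2], base[4]])]
        assert len(build_positive_set(records)) == 7


class TestNegativeSet:
    universe = list(itertools.product([f"d{i}" for i in range(4)],
                                      [f"t{i}" for i in range(4)]))

    def test_exhaustive_sampling(self):
        positives = self.universe[:6]
        negs = build_negative_set(self.universe, positives, n=10, seed=0)
        assert len(negs) == 10 and len(set(negs)) == 10

    def test_reproducible_by_seed(self):
        a = build_negative_set(self.universe, self.universe[:3], 5, seed=9)
        b = build_negative_set(self.universe, self.universe[:3], 5, seed=9)
        assert a == b

    def test_never_overlaps_positives_over_many_seeds(self):
        positives = set(self.universe[::2])
        for seed in range(100):
            negs = build_negative_set(self.universe, positives, 6, seed=seed)
            assert not set(negs) & positives

    def test_oversampling_fatal(self):
        with pytest.raises(ValueError):
            build_negative_set(self.universe, self.universe[:10], 10, seed=0)


class TestScreenNegatives:
    def test_rule_instance(self):
        flagged = screen_negatives(
            [("d1", "t1")], {"d1": ["d2"]}, [("d2", "t1")]
        )
        assert flagged == [("d1", "t1")]

    def test_no_similar_compounds_no_flags(self):
        assert screen_negatives([("d1", "t1")], {}, [("d2", "t1")]) == []

    def test_planted_missannotations_exactly_found(self):
        rng = np.random.default_rng(5)
        negatives = [(f"d{i}", f"t{i % 10}") for i in range(50)]
        planted = [negatives[3], negatives[17], negatives[41]]
        similar = {d: [f"sim_{d}"] for d, _ in planted}
        interactions = [(f"sim_{d}", t) for d, t in planted]
        flagged = screen_negatives(negatives, similar, interactions)
        assert sorted(flagged) == sorted(planted)


class TestIdentityExclusion:
    def test_planted_identity_edges_removed(self, toy_network):
        # plant 5 identity edges from benchmark entities
        for i in range(3):
            toy_network.add_query_node(f"B{i}")
            toy_network.add_similarity_edge(f"B{i}", "LC0", 1.0, kind="ligand")
        toy_network.add_similarity_edge("Q1", "LC1", 1.0, kind="ligand")
        toy_network.add_similarity_edge("T1", "SC1", 1.0, kind="site_model")
        bench = ["B0", "B1", "B2", "Q1", "T1"]
        before = toy_network.graph.number_of_edges()
        removed = exclude_identity_links(toy_network, benchmark_ligands=bench[:4],
                                         benchmark_sites=["T1"])
        # Q1-LC0 and T1-SC0 were already similarity 1.0 in the fixture
        assert removed == 7
        assert toy_network.graph.number_of_edges() == before - 7
        assert not toy_network.graph.has_edge("B0", "LC0")

    def test_no_identical_entities_no_change(self, toy_network):
        toy_network.graph.edges["Q1", "LC0"]["similarity"] = 0.95
        toy_network.graph.edges["T1", "SC0"]["similarity"] = 0.9
        before = set(toy_network.graph.edges)
        removed = exclude_identity_links(toy_network,
                                         benchmark_ligands=["Q1"],
                                         benchmark_sites=["T1"])
        assert removed == 0
        assert set(toy_network.graph.edges) == before

    def test_interaction_edges_never_removed(self, toy_network):
        exclude_identity_links(toy_network, benchmark_ligands=["LC0"])
        assert toy_network.graph.has_edge("LC0", "SC0")


def oracle_metrics(preds, truth, score_col):
    """From-scratch confusion matrix + Mann-Whitney AUC oracle."""
    best = {}
    for _, r in preds.iterrows():
        k = (r["query_id"], r["protein_id"])
        best[k] = max(best.get(k, -np.inf), r[score_col])
    floor = (min(best.values()) - 1.0) if best else -1.0
    y, s = [], []
    for _, r in truth.iterrows():
        y.append(int(r["label"]))
        s.append(best.get((r["query_id"], r["protein_id"]), floor))
    y, s = np.asarray(y), np.asarray(s)
    called = set(best)
    tp = sum(1 for _, r in truth.iterrows()
             if r["label"] and (r["query_id"], r["protein_id"]) in called)
    fp = sum(1 for _, r in truth.iterrows()
             if not r["label"] and (r["query_id"], r["protein_id"]) in called)
    fn = int(truth["label"].sum()) - tp
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    # Mann-Whitney with tie correction
    from scipy.stats import rankdata

    ranks = rankdata(s)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return precision, recall, auc


class TestEvaluate:
    def test_closed_form_counts(self):
        truth = pd.DataFrame({
            "query_id": [f"q{i}" for i in range(6)],
            "protein_id": ["p"] * 6,
            "label": [1, 1, 1, 0, 0, 1],
        })
        # predict q0, q1 (TP) and q3, q4 (FP); miss q2, q5 (FN)
        preds = pd.DataFrame({
            "query_id": ["q0", "q1", "q3", "q4"],
            "protein_id": ["p"] * 4,
            "score": [0.9, 0.8, 0.7, 0.6],
        })
        m = evaluate(preds, truth)
        assert (m["tp"], m["fp"], m["fn"]) == (2, 2, 2)
        assert m["precision"] == 0.5 and m["recall"] == 0.5

    def test_perfect_ranking_auc_one(self):
        truth = pd.DataFrame({
            "query_id": [f"q{i}" for i in range(20)],
            "protein_id": ["p"] * 20,
            "label": [1] * 10 + [0] * 10,
        })
        preds = pd.DataFrame({
            "query_id": truth["query_id"],
            "protein_id": "p",
            "score": np.linspace(1.0, 0.05, 20),
        })
        assert evaluate(preds, truth)["auc"] == pytest.approx(1.0)

    def test_random_scores_chance_auc(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            truth = pd.DataFrame({
                "query_id": [f"q{i}" for i in range(200)],
                "protein_id": "p",
                "label": [1] * 100 + [0] * 100,
            })
            preds = pd.DataFrame({
                "query_id": truth["query_id"],
                "protein_id": "p",
                "score": rng.uniform(size=200),
            })
            aucs.append(evaluate(preds, truth)["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_truth_gives_na_auc(self):
        truth = pd.DataFrame({"query_id": ["q0"], "protein_id": ["p"],
                              "label": [1]})
        preds = pd.DataFrame({"query_id": ["q0"], "protein_id": ["p"],
                              "score": [0.5]})
        assert evaluate(preds, truth)["auc"] is None

    def test_matches_fromscratch_oracle_on_random_fixtures(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 40))
            truth = pd.DataFrame({
                "query_id": [f"q{i}" for i in range(n)],
                "protein_id": [f"p{i % 5}" for i in range(n)],
                "label": rng.integers(0, 2, n),
            })
            if truth["label"].nunique() < 2:
                continue
            mask = rng.random(n) < 0.7
            preds = pd.DataFrame({
                "query_id": truth["query_id"][mask],
                "protein_id": truth["protein_id"][mask],
                "score": rng.uniform(size=int(mask.sum())),
            })
            if not len(preds):
                continue
            m = evaluate(preds, truth)
            p, r, auc = oracle_metrics(preds, truth, "score")
            assert m["precision"] == pytest.approx(p, nan_ok=True)
            assert m["recall"] == pytest.approx(r, nan_ok=True)
            assert m["auc"] == pytest.approx(auc)

    def test_enrichment_monotone_and_ends_at_one(self):
        rng = np.random.default_rng(1)
        truth = pd.DataFrame({
            "query_id": [f"q{i}" for i in range(50)],
            "protein_id": "p",
            "label": rng.integers(0, 2, 50),
        })
        preds = pd.DataFrame({
            "query_id": truth["query_id"],
            "protein_id": "p",
            "score": rng.uniform(size=50),
        })
        curve = evaluate(preds, truth)["enrichment_curve"]
        recovered = [y for _, y in curve]
        assert all(b >= a for a, b in zip(recovered, recovered[1:]))
        assert recovered[-1] == pytest.approx(1.0)
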