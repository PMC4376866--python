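"""Bounded shortest-path search, path scoring and Z-score contracts."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pocketpath.predict import (
    bounded_dijkstra,
    predict_all,
    score_path,
    zscore_predictions,
)


def chain_graph():
    g = nx.Graph()
    g.add_edge("q", "L", distance=1.0)
    g.add_edge("L", "S", distance=1.0)
    g.add_edge("S", "T", distance=1.0)
    return g


def brute_force_shortest(graph, source, d_max):
    """Oracle: enumerate every simple path and keep the best per target
    under the same (distance, hops, lexicographic path) ordering."""
    best = {source: (0.0, (source,))}
    for target in graph.nodes:
        if target == source:
            continue
        candidates = []
        for path in nx.all_simple_paths(graph, source, target):
            dist = sum(graph.edges[a, b]["distance"]
                       for a, b in zip(path, path[1:]))
            if dist <= d_max + 1e-12:
                candidates.append((dist, len(path) - 1, tuple(path)))
        if candidates:
            best[target] = (min(candidates)[0], min(candidates)[2])
    return best


def random_graph(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    g = nx.gnp_random_graph(n, 0.4, seed=seed)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    for a, b in g.edges:
        g.edges[a, b]["distance"] = float(rng.uniform(1.0, 3.0))
    return g


class TestBoundedDijkstra:
    def test_single_chain_within_bound(self):
        out = bounded_dijkstra(chain_graph(), "q", d_max=10.0)
        assert out["T"] == (3.0, ("q", "L", "S", "T"))

    def test_bound_excludes_far_nodes(self):
        out = bounded_dijkstra(chain_graph(), "q", d_max=2.5)
        assert "T" not in out
        assert "S" in out

    def test_unknown_source_fatal(self):
        with pytest.raises(KeyError):
            bounded_dijkstra(chain_graph(), "zz", 1.0)

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        for seed in range(50):
            g = random_graph(seed)
            source = sorted(g.nodes)[0]
            d_max = 5.0
            ours = bounded_dijkstra(g, source, d_max=d_max)
            oracle = brute_force_shortest(g, source, d_max)
            assert set(ours) == set(oracle)
            for node in oracle:
                assert ours[node][0] == pytest.approx(oracle[node][0])

    def test_matches_networkx_distances(self):
        # independent library cross-check, ignoring the bound
        for seed in range(10):
            g = random_graph(seed)
            source = sorted(g.nodes)[0]
            ours = bounded_dijkstra(g, source, d_max=1e9)
            ref = nx.single_source_dijkstra_path_length(g, source,
                                                        weight="distance")
            assert set(ours) == set(ref)
            for node, d in ref.items():
                assert ours[node][0] == pytest.approx(d)

    def test_deterministic_tie_break_prefers_fewer_hops_then_lex(self):
        g = nx.Graph()
        # two equal-distance routes q->t: direct (1 hop, 2.0) and via a (2 hops)
        g.add_edge("q", "t", distance=2.0)
        g.add_edge("q", "a", distance=1.0)
        g.add_edge("a", "t", distance=1.0)
        assert bounded_dijkstra(g, "q", 10)["t"][1] == ("q", "t")
        # equal distance and hops: lexicographically smaller middle node wins
        g2 = nx.Graph()
        for mid in ("b", "a"):
            g2.add_edge("q", mid, distance=1.0)
            g2.add_edge(mid, "t", distance=1.0)
        assert bounded_dijkstra(g2, "q", 10)["t"][1] == ("q", "a", "t")

    def test_adding_edge_never_increases_distance(self):
        for seed in range(10):
            g = random_graph(seed)
            source = sorted(g.nodes)[0]
            before = bounded_dijkstra(g, source, d_max=1e9)
            non_edges = [e for e in itertools.combinations(sorted(g.nodes), 2)
                         if not g.has_edge(*e)]
            if not non_edges:
                continue
            a, b = non_edges[0]
            g.add_edge(a, b, distance=1.0)
            after = bounded_dijkstra(g, source, d_max=1e9)
            for node in before:
                assert after[node][0] <= before[node][0] + 1e-12


class TestScorePath:
    def test_inverse_distance(self):
        assert score_path(1.0) == 1.0
        assert score_path(4.0) == 0.25

    def test_longer_path_scores_lower(self):
        assert score_path(3.0) > score_path(3.5)

    def test_nonpositive_distance_fatal(self):
        with pytest.raises(ValueError):
            score_path(0.0)


def frame(scores, sites=None):
    sites = sites or [f"t{i}" for i in range(len(scores))]
    return pd.DataFrame({
        "query_id": [f"q{i}" for i in range(len(scores))],
        "protein_id": ["p"] * len(scores),
        "site_id": sites,
        "score": scores,
        "path": ["q|x|t"] * len(scores),
    })


class TestZScores:
    def test_population_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        df = frame(rng.uniform(0.1, 1.0, size=200).tolist())
        out, stats = zscore_predictions(df)
        gz = out["global_z"].to_numpy()
        assert abs(gz.mean()) < 1e-9
        assert abs(gz.std(ddof=0) - 1.0) < 1e-9

    def test_local_groups_standardized(self):
        rng = np.random.default_rng(2)
        df = frame(rng.uniform(0.1, 1.0, size=100).tolist(),
                   sites=[f"t{i % 4}" for i in range(100)])
        out, _ = zscore_predictions(df)
        for _, grp in out.groupby("site_id"):
            lz = grp["local_z"].to_numpy()
            assert abs(lz.mean()) < 1e-9
            assert abs(lz.std(ddof=0) - 1.0) < 1e-9

    def test_score_equal_to_mean_gives_zero_gz(self):
        df = frame([0.2, 0.4, 0.6])
        out, _ = zscore_predictions(df, normalize="none")
        assert out.loc[1, "global_z"] == pytest.approx(0.0)

    def test_degenerate_sigma_yields_zero_with_warning(self):
        df = frame([0.5, 0.5, 0.5])
        with pytest.warns(UserWarning):
            out, _ = zscore_predictions(df, normalize="none")
        assert (out["global_z"] == 0).all()
        # single prediction for a target -> local sigma 0 -> Lz 0
        df2 = frame([0.2, 0.8], sites=["t1", "t2"])
        with pytest.warns(UserWarning):
            out2, _ = zscore_predictions(df2, normalize="none")
        assert (out2["local_z"] == 0).all()

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            zscore_predictions(frame([]))

    def test_zscores_invariant_to_minmax_normalization(self):
        rng = np.random.default_rng(3)
        df = frame(rng.uniform(0.1, 1.0, size=50).tolist(),
                   sites=[f"t{i % 3}" for i in range(50)])
        a, _ = zscore_predictions(df, normalize="none")
        b, _ = zscore_predictions(df, normalize="minmax")
        assert np.allclose(a["global_z"], b["global_z"])
        assert np.allclose(a["local_z"], b["local_z"])


class TestPredictAll:
    def test_rows_per_reachable_site(self, toy_network):
        df = predict_all(toy_network)
        assert set(df["query_id"]) == {"Q1"}
        assert set(df["site_id"]) == {"T1"}
        # Q1 -> LC0 (1.0) -> SC0 (1.0) -> T1 (1.0)
        assert df["score"].iloc[0] == pytest.approx(1.0 / 3.0)
        assert df["path"].iloc[0] == "Q1|LC0|SC0|T1"

    def test_protein_score_is_max_over_sites(self, toy_network):
        # add a second, worse-connected site of the same protein
        from conftest import make_site

        t2 = make_site("T2", "HP1", source="model", quality=1.5)
        toy_network.add_target_site_node(t2)
        toy_network.add_similarity_edge("T2", "SC1", 0.5, kind="site_model")
        df = predict_all(toy_network)
        assert len(df) == 2
        assert df["protein_score"].nunique() == 1
        assert df["protein_score"].iloc[0] == pytest.approx(df["score"].max())

    def test_removing_path_edge_removes_or_worsens_hit(self, toy_network):
        before = predict_all(toy_network)
        toy_network.graph.remove_edge("LC0", "SC0")
        after = predict_all(toy_network)
        if len(after):
            assert after["score"].iloc[0] < before["score"].iloc[0]
        else:
            assert len(after) == 0

    def test_unreachable_query_yields_no_rows(self, toy_network):
        toy_network.add_query_node("Q9", unreachable=True)
        df = predict_all(toy_network)
        assert "Q9" not in set(df["query_id"])
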