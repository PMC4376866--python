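"""Domain types, tabular readers and network serialization."""

import math

import numpy as np
import pytest

from pocketpath.model_io import (
    BindingSite,
    BipartiteNetwork,
    ClusterNode,
    Compound,
    InteractionEdge,
    NetworkInvariantError,
    SimilarityEdge,
    EPSILON,
    read_compound_table,
    read_edge_list,
    read_network,
    similarity_to_distance,
    write_network,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestTypes:
    def test_distance_is_inverse_similarity_with_clamp(self):
        assert similarity_to_distance(0.5) == 2.0
        assert similarity_to_distance(1.0) == 1.0
        # above 1 clamps to 1; near zero clamps at epsilon
        assert similarity_to_distance(2.0) == 1.0
        assert similarity_to_distance(0.0) == 1.0 / EPSILON

    def test_similarity_edge_rejects_self_loop_and_nonpositive(self):
        with pytest.raises(ValueError):
            SimilarityEdge("x", "x", 0.9)
        with pytest.raises(ValueError):
            SimilarityEdge("x", "y", 0.0)

    def test_model_site_requires_quality(self):
        with pytest.raises(ValueError):
            BindingSite("m", "p", [("A", 1, "GLY")], source="model")

    def test_wqed_range_enforced(self):
        with pytest.raises(ValueError):
            Compound("c", wqed=1.2)

    def test_prediction_path_endpoints_checked(self):
        from pocketpath.model_io import Prediction

        with pytest.raises(ValueError):
            Prediction("q", "t", "p", 0.5, path=("q", "x"))


class TestCompoundTable:
    def test_tsv_roundtrip_identity(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "id\tsmiles\twqed\nA\tCCO\t0.5\nB\tc1ccccc1\t0.7\nC\tCC\t0.2\n")
        comps = read_compound_table(p)
        assert [c.id for c in comps] == ["A", "B", "C"]
        assert comps[1].wqed == 0.7
        assert all(c.fingerprint is not None for c in comps)

    def test_duplicate_id_fatal(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "id\tsmiles\nDB00945\tCCO\nDB00945\tCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_compound_table(p)

    def test_smiles_list_autoids_and_equal_fp_lengths(self, tmp_path):
        p = write(tmp_path, "c.smi", "CCO\nc1ccccc1\n")
        comps = read_compound_table(p, format="smiles-list")
        assert len(comps) == 2
        lengths = {len(c.fingerprint) for c in comps}
        assert len(lengths) == 1

    def test_bad_smiles_is_record_level(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "id\tsmiles\nOK\tCCO\nBAD\tnot_a_smiles(((\n")
        with pytest.warns(UserWarning, match="BAD"):
            comps = read_compound_table(p)
        assert [c.id for c in comps] == ["OK"]
        with pytest.raises(ValueError):
            read_compound_table(p, on_bad_smiles="raise")

    def test_prefeaturized_rows_need_no_smiles(self, tmp_path):
        p = write(tmp_path, "c.tsv", "id\twqed\tmw\nA\t0.4\t250.0\n")
        (c,) = read_compound_table(p)
        assert c.smiles is None and c.descriptors["mw"] == 250.0


class TestEdgeList:
    def test_symmetric_dedup_keeps_max(self, tmp_path):
        p = write(tmp_path, "e.tsv",
                  "a\tb\tvalue\tkind\nx\ty\t0.8\tligand\ny\tx\t0.6\tligand\n")
        edges = read_edge_list(p)
        assert len(edges) == 1
        assert edges[0].similarity == 0.8

    def test_self_loop_dropped_with_warning(self, tmp_path):
        p = write(tmp_path, "e.tsv", "a\tb\tvalue\tkind\nx\tx\t0.9\tligand\n")
        with pytest.warns(UserWarning, match="self-loop"):
            assert read_edge_list(p) == []

    def test_distinct_rows_all_kept(self, tmp_path):
        rows = "\n".join(f"n{i}\tm{i}\t0.{i + 1}\tligand" for i in range(5))
        p = write(tmp_path, "e.tsv", "a\tb\tvalue\tkind\n" + rows + "\n")
        assert len(read_edge_list(p)) == 5

    def test_non_numeric_value_fatal(self, tmp_path):
        p = write(tmp_path, "e.tsv", "a\tb\tvalue\tkind\nx\ty\thigh\tligand\n")
        with pytest.raises(ValueError):
            read_edge_list(p)

    def test_interaction_rows_kept_with_evidence(self, tmp_path):
        p = write(tmp_path, "e.tsv",
                  "a\tb\tvalue\tkind\tevidence\nl\ts\t1.0\tinteraction\tC1\n")
        (e,) = read_edge_list(p)
        assert isinstance(e, InteractionEdge) and e.evidence == "C1"


class TestEdgeListProperties:
    from hypothesis import given, settings, strategies as st

    node_ids = st.sampled_from([f"n{i}" for i in range(6)])
    rows = st.lists(
        st.tuples(node_ids, node_ids,
                  st.floats(min_value=0.01, max_value=1.0,
                            allow_nan=False)),
        min_size=1, max_size=30,
    )

    @given(rows=rows)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_reader_output_satisfies_edge_invariants(self, rows, tmp_path_factory):
        import warnings as _warnings

        tmp = tmp_path_factory.mktemp("fuzz")
        lines = ["a\tb\tvalue\tkind"]
        lines += [f"{a}\t{b}\t{v}\tligand" for a, b, v in rows]
        p = tmp / "edges.tsv"
        p.write_text("\n".join(lines) + "\n")
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            edges = read_edge_list(p)
        seen = set()
        for e in edges:
            assert e.a != e.b
            assert e.similarity > 0
            key = frozenset((e.a, e.b))
            assert key not in seen  # symmetric dedup leaves one edge per pair
            seen.add(key)
            # kept value is the max over both orders in the input
            expected = max(v for a, b, v in rows
                           if frozenset((a, b)) == key and a != b)
            assert e.similarity == pytest.approx(expected)


class TestNetworkSerialization:
    @pytest.mark.parametrize("fmt,suffix", [("json", ".json"),
                                            ("graphml", ".graphml")])
    def test_roundtrip_lossless(self, toy_network, tmp_path, fmt, suffix):
        path = tmp_path / f"net{suffix}"
        write_network(toy_network, path, format=fmt)
        back = read_network(path)
        assert set(back.graph.nodes) == set(toy_network.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == \
            set(map(frozenset, toy_network.graph.edges))
        for a, b, d in toy_network.graph.edges(data=True):
            d2 = back.graph.edges[a, b]
            assert math.isclose(d2["similarity"], d["similarity"],
                                abs_tol=1e-9)
            assert d2["kind"] == d["kind"]
        for n, d in toy_network.graph.nodes(data=True):
            assert tuple(back.graph.nodes[n]["members"]) == tuple(d["members"])

    def test_cross_partition_similarity_edge_fails_on_read(self, toy_network,
                                                           tmp_path):
        path = tmp_path / "net.json"
        write_network(toy_network, path)
        text = path.read_text().replace('"kind": "interaction"',
                                        '"kind": "ligand"')
        path.write_text(text)
        with pytest.raises(NetworkInvariantError, match="crosses partitions"):
            read_network(path)

    def test_empty_network_roundtrip(self, tmp_path):
        net = BipartiteNetwork()
        path = tmp_path / "empty.json"
        write_network(net, path)
        back = read_network(path)
        assert back.graph.number_of_nodes() == 0

    def test_duplicate_cluster_member_rejected(self):
        net = BipartiteNetwork()
        net.add_cluster(ClusterNode("C1", ("a",), "ligand"))
        with pytest.raises(NetworkInvariantError):
            net.add_cluster(ClusterNode("C2", ("a",), "ligand"))
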