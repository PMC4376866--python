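"""Redundancy reduction of a similarity sub-network.

Mutually similar nodes are grouped into cluster vertices and the edges
between clusters are rebuilt carrying the maximum weight over all
member-pair edges.  Two grouping modes exist:

``clique``
    greedy maximal-clique cover (largest clique first, lexicographic
    tie-break): every two members of a cluster are directly similar.
``kcore``
    each multi-node cluster is a maximal connected subgraph of the k-core;
    nodes outside the k-core stay singletons.

Both are deterministic partitions (no overlaps); singletons are kept.
"""

from __future__ import annotations

import logging

import networkx as nx

from .model_io import ClusterNode

log = logging.getLogger(__name__)


def _greedy_clique_cover(graph: nx.Graph) -> list[tuple[str, ...]]:
    """Largest-first clique cover; ties broken by the lexicographically
    smallest sorted member tuple.  Every returned group is a clique."""
    remaining = set(graph.nodes)
    groups: list[tuple[str, ...]] = []
    while remaining:
        sub = graph.subgraph(remaining)
        best: tuple[int, tuple[str, ...]] | None = None
        for clique in nx.find_cliques(sub):
            key = (-len(clique), tuple(sorted(clique)))
            if best is None or key < best:
                best = key
        members = best[1]
        groups.append(members)
        remaining.difference_update(members)
    return groups


def _kcore_cover(graph: nx.Graph, k: int) -> list[tuple[str, ...]]:
    core = nx.k_core(graph, k)
    groups = [tuple(sorted(cc)) for cc in nx.connected_components(core)]
    in_core = set(core.nodes)
    groups.extend((n,) for n in graph.nodes if n not in in_core)
    return groups


def find_clusters(
    graph: nx.Graph,
    mode: str = "clique",
    k: int = 2,
    partition: str = "ligand",
    prefix: str | None = None,
) -> list[ClusterNode]:
    """Partition the nodes of a similarity graph into cluster vertices.

    Cluster ids are assigned after sorting groups by descending size then
    smallest member, so the labelling is reproducible.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if graph.is_directed():
        raise ValueError("similarity graphs must be undirected")
    if mode == "clique":
        groups = _greedy_clique_cover(graph)
    elif mode == "kcore":
        groups = _kcore_cover(graph, k)
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")

    groups.sort(key=lambda g: (-len(g), min(g)))
    if prefix is None:
        prefix = "LC" if partition == "ligand" else "SC"
    clusters = [
        ClusterNode(id=f"{prefix}{i:04d}", members=tuple(sorted(g)),
                    partition=partition)
        for i, g in enumerate(groups)
    ]
    log.info("%s clustering: %d nodes -> %d clusters (%d multi-node)",
             mode, graph.number_of_nodes(), len(clusters),
             sum(1 for c in clusters if len(c.members) > 1))
    return clusters


def condense_network(
    graph: nx.Graph,
    clusters: list[ClusterNode],
    weight: str = "similarity",
) -> nx.Graph:
    """Build the cluster-level graph: an edge joins two clusters iff at
    least one original edge crosses them, weighted by the maximum crossing
    similarity.  Self-loops never arise (intra-cluster edges are absorbed).
    """
    member_of: dict[str, str] = {}
    for c in clusters:
        for m in c.members:
            if m in member_of:
                raise ValueError(f"member {m!r} appears in two clusters")
            member_of[m] = c.id
    orphans = [n for n in graph.nodes if n not in member_of]
    if orphans:
        raise ValueError(f"nodes absent from every cluster: {orphans[:10]}")

    out = nx.Graph()
    out.add_nodes_from(c.id for c in clusters)
    for a, b, d in graph.edges(data=True):
        ca, cb = member_of[a], member_of[b]
        if ca == cb:
            continue
        w = float(d[weight])
        if out.has_edge(ca, cb):
            if w > out.edges[ca, cb][weight]:
                out.edges[ca, cb][weight] = w
        else:
            out.add_edge(ca, cb, **{weight: w})
    log.info("condensation: %d/%d nodes, %d/%d edges",
             out.number_of_nodes(), graph.number_of_nodes(),
             out.number_of_edges(), graph.number_of_edges())
    return out
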