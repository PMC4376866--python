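"""Assembly of the full bipartite network.

Joins the condensed ligand and binding-site sub-networks with observed
interaction edges, then integrates (a) modeled target binding sites via a
staged quality / identity / redundancy filter and (b) query compounds via
a pair classifier or a precomputed similarity table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from . import _chem
from .model_io import (
    LIGAND,
    SITE,
    BindingSite,
    BipartiteNetwork,
    ClusterNode,
    Compound,
    SimilarityEdge,
)
from .condense import condense_network, find_clusters
from .similarity import normalize_z

log = logging.getLogger(__name__)

#: ModPipe-style quality cut for modeled sites
MODEL_QUALITY_MIN = 1.1
#: acceptance: both site sequence and structure identity must exceed this
IDENTITY_MIN_PCT = 40.0
#: redundancy: drop sites with more than this sequence identity to a kept one
REDUNDANCY_PCT = 80.0
#: minimum residues for a modeled site to be kept
MIN_SITE_RESIDUES = 6
#: Z threshold for model-site similarity links (strict)
MODEL_ZMIN = 1.0
#: pair-classifier probability needed to create a query edge
QUERY_EDGE_THRESHOLD = 0.5


def build_subnetwork(
    edges: Sequence[SimilarityEdge],
    partition: str,
    nodes: Iterable[str] = (),
    mode: str = "clique",
    k: int = 2,
) -> tuple[list[ClusterNode], nx.Graph]:
    """Raw similarity edges -> (clusters, condensed cluster graph)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        if g.has_edge(e.a, e.b):
            if e.similarity > g.edges[e.a, e.b]["similarity"]:
                g.edges[e.a, e.b]["similarity"] = e.similarity
        else:
            g.add_edge(e.a, e.b, similarity=e.similarity)
    clusters = find_clusters(g, mode=mode, k=k, partition=partition)
    return clusters, condense_network(g, clusters)


def assemble_network(
    ligand_clusters: list[ClusterNode],
    ligand_graph: nx.Graph,
    site_clusters: list[ClusterNode],
    site_graph: nx.Graph,
    compounds: Iterable[Compound] = (),
    sites: Iterable[BindingSite] = (),
) -> BipartiteNetwork:
    """Stitch the two condensed sub-networks into one bipartite network."""
    net = BipartiteNetwork()
    for c in ligand_clusters:
        net.add_cluster(c)
    for c in site_clusters:
        net.add_cluster(c)
    for a, b, d in ligand_graph.edges(data=True):
        net.add_similarity_edge(a, b, d["similarity"], kind="ligand")
    for a, b, d in site_graph.edges(data=True):
        net.add_similarity_edge(a, b, d["similarity"], kind="site")
    for c in compounds:
        net.compounds[c.id] = c
    for s in sites:
        net.sites[s.id] = s
    net.validate()
    return net


def link_interactions(
    network: BipartiteNetwork,
    observed: Iterable[tuple[str, str, str]],
) -> int:
    """Add one interaction edge per (ligand cluster, site cluster) pair with
    at least one observed member pair; evidence accumulates on the edge.
    Unresolvable ids are skipped with a warning; returns the skip count.
    """
    skipped = 0
    for ligand_id, site_id, evidence in observed:
        lc = network.resolve_member(ligand_id)
        sc = network.resolve_member(site_id)
        if lc is None or sc is None:
            log.warning("interaction (%s, %s) references unknown id; skipped",
                        ligand_id, site_id)
            skipped += 1
            continue
        network.add_interaction_edge(lc, sc, evidence=evidence)
    network.validate()
    return skipped


def _residue_identity_pct(a: BindingSite, b: BindingSite) -> float:
    """Sequence identity between two sites of the same protein, as the
    shared-residue fraction of the smaller site (percent)."""
    ra, rb = set(a.residues), set(b.residues)
    denom = min(len(ra), len(rb))
    if denom == 0:
        return 0.0
    return 100.0 * len(ra & rb) / denom


@dataclass
class IntegrationReport:
    """Per-stage bookkeeping of the model-site integration filter."""

    n_input: int = 0
    n_after_quality: int = 0
    n_after_identity: int = 0
    n_after_redundancy: int = 0
    n_edges_added: int = 0
    n_rows_skipped: int = 0
    kept_sites: list[str] = field(default_factory=list)


def integrate_target_sites(
    network: BipartiteNetwork,
    model_sites: Sequence[BindingSite],
    comparisons: pd.DataFrame,
    quality_min: float = MODEL_QUALITY_MIN,
    identity_min: float = IDENTITY_MIN_PCT,
    redundancy_pct: float = REDUNDANCY_PCT,
    min_residues: int = MIN_SITE_RESIDUES,
    zmin: float = MODEL_ZMIN,
) -> IntegrationReport:
    """Integrate modeled target binding sites into the network.

    ``comparisons`` holds one row per (model_site, known_site) structural
    comparison with columns ``model_site, known_site, seq_id_site,
    struct_id_site, probis_z``.  Stages, applied in order:

    1. drop model sites with quality below ``quality_min``;
    2. accept a site only if some comparison row has both site sequence
       and structure identity strictly above ``identity_min`` percent;
    3. drop small sites (fewer than ``min_residues`` residues) and
       redundant sites (more than ``redundancy_pct`` residue identity to an
       already-kept site of the same protein; scan order: descending
       residue count, then ascending id);
    4. add a similarity edge for every comparison row of a kept site with
       Z strictly above ``zmin``, weighted by the normalized Z-score.

    Model sites enter as their own node each (they are not condensed).
    """
    report = IntegrationReport(n_input=len(model_sites))

    stage1 = [s for s in model_sites
              if s.quality is not None and s.quality >= quality_min]
    report.n_after_quality = len(stage1)

    cmp_rows = comparisons.copy()
    unknown = ~cmp_rows["model_site"].astype(str).isin(
        {s.id for s in model_sites}
    ) | cmp_rows["known_site"].astype(str).map(
        lambda sid: network.resolve_member(str(sid)) is None
    )
    report.n_rows_skipped = int(unknown.sum())
    cmp_rows = cmp_rows[~unknown]

    accepted_ids = set(
        cmp_rows.loc[
            (cmp_rows["seq_id_site"] > identity_min)
            & (cmp_rows["struct_id_site"] > identity_min),
            "model_site",
        ].astype(str)
    )
    stage2 = [s for s in stage1 if s.id in accepted_ids]
    report.n_after_identity = len(stage2)

    # size filter, then greedy redundancy scan (first-seen wins)
    sized = [s for s in stage2 if len(s.residues) >= min_residues]
    kept: list[BindingSite] = []
    by_protein: dict[str, list[BindingSite]] = {}
    for s in sorted(sized, key=lambda s: (-len(s.residues), s.id)):
        redundant = any(
            _residue_identity_pct(s, prev) > redundancy_pct
            for prev in by_protein.get(s.protein_id, ())
        )
        if not redundant:
            kept.append(s)
            by_protein.setdefault(s.protein_id, []).append(s)
    report.n_after_redundancy = len(kept)
    report.kept_sites = sorted(s.id for s in kept)

    kept_ids = {s.id for s in kept}
    for s in sorted(kept, key=lambda s: s.id):
        network.add_target_site_node(s)
    for _, row in cmp_rows.iterrows():
        mid = str(row["model_site"])
        if mid not in kept_ids:
            continue
        z = float(row["probis_z"])
        if z <= zmin:
            continue
        known_cluster = network.resolve_member(str(row["known_site"]))
        network.add_similarity_edge(
            mid, known_cluster, normalize_z(z, zmin), kind="site_model"
        )
        report.n_edges_added += 1

    log.info(
        "model-site integration: %d in, %d after quality, %d after identity, "
        "%d kept, %d edges, %d rows skipped",
        report.n_input, report.n_after_quality, report.n_after_identity,
        report.n_after_redundancy, report.n_edges_added, report.n_rows_skipped,
    )
    network.validate()
    return report


PairScorer = Callable[[Compound, Compound], float]


def _canonical(compound: Compound) -> str | None:
    if compound.smiles is None:
        return None
    try:
        return _chem.canonical_smiles(compound.smiles)
    except ValueError:
        return None


def integrate_query_compounds(
    network: BipartiteNetwork,
    queries: Sequence[Compound],
    pair_scorer: PairScorer | Mapping[tuple[str, str], float] | None = None,
    edge_threshold: float = QUERY_EDGE_THRESHOLD,
) -> list[str]:
    """Attach query compounds to ligand clusters.

    For each (query, cluster) pair the scorer is evaluated against every
    member compound; if the best probability reaches ``edge_threshold`` a
    single edge with that maximum probability is created.  A query whose
    canonical structure equals a member's gets similarity exactly 1.0.
    Queries with zero links are kept as nodes flagged unreachable; the
    list of unreachable query ids is returned.
    """
    if isinstance(pair_scorer, Mapping):
        table = pair_scorer

        def score(q: Compound, member_id: str) -> float:
            return table.get((q.id, member_id),
                             table.get((member_id, q.id), 0.0))
    elif pair_scorer is not None:
        def score(q: Compound, member_id: str) -> float:
            member = network.compounds.get(member_id)
            if member is None:
                return 0.0
            return float(pair_scorer(q, member))
    else:
        raise ValueError("a pair scorer or similarity table is required")

    canon_cache = {cid: _canonical(c) for cid, c in network.compounds.items()}
    unreachable: list[str] = []
    for q in queries:
        network.add_query_node(q.id)
        network.compounds.setdefault(q.id, q)
        q_canon = _canonical(q)
        linked = False
        for cluster in network.clusters(LIGAND):
            best = 0.0
            for member_id in cluster.members:
                if q_canon is not None and canon_cache.get(member_id) == q_canon:
                    best = 1.0
                    break
                best = max(best, score(q, member_id))
            if best >= edge_threshold:
                network.add_similarity_edge(q.id, cluster.id, best, kind="ligand")
                linked = True
        if not linked:
            network.graph.nodes[q.id]["unreachable"] = True
            unreachable.append(q.id)
    if unreachable:
        log.info("%d quer%s left unreachable: %s", len(unreachable),
                 "y" if len(unreachable) == 1 else "ies", unreachable[:10])
    network.validate()
    return unreachable
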