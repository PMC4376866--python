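"""Domain types for the bipartite ligand / binding-site network, plus
readers and writers for every tabular and graph format the pipeline touches.

The canonical tabular dialect is TSV: tab-separated, ``#`` comments, header
row required.  Networks serialize to a JSON dialect (full fidelity,
including the compound/site registries) or GraphML (topology, weights and
cluster membership only).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import _chem

#: similarity clamp floor used when converting similarity to path distance;
#: keeps distances finite while leaving near-zero similarities unreachable
EPSILON = 1e-6

LIGAND = "ligand"
SITE = "site"

SIMILARITY_KINDS = ("ligand", "site", "site_model")
EDGE_KINDS = SIMILARITY_KINDS + ("interaction",)


class NetworkInvariantError(ValueError):
    """A structural invariant of the bipartite network was violated."""


def similarity_to_distance(similarity: float, eps: float = EPSILON) -> float:
    """Edge distance = 1 / similarity, with similarity clamped to (eps, 1].

    High-similarity hops cost ~1; dissimilar hops are long, so short
    high-similarity paths dominate any bounded search.
    """
    return 1.0 / min(max(float(similarity), eps), 1.0)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Compound:
    """A small molecule: a query drug or a network ligand.

    ``smiles`` is optional so that pre-featurized records (fingerprint and
    descriptor columns from an upstream tool) can flow through the pipeline
    without any chemistry toolkit involvement.
    """

    id: str
    smiles: str | None = None
    wqed: float | None = None
    fingerprint: np.ndarray | None = None
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.wqed is not None and not (0.0 <= self.wqed <= 1.0):
            raise ValueError(f"compound {self.id}: wqed {self.wqed} outside [0, 1]")


@dataclass
class BindingSite:
    """A ligand-binding pocket tied to a parent protein.

    ``residues`` is a list of (chain, position, amino-acid code) tuples.
    Model-derived sites must carry a quality score (a ModPipe-style
    composite); experimentally determined sites need none.
    """

    id: str
    protein_id: str
    residues: list[tuple[str, int, str]]
    source: str = "experimental"
    quality: float | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"binding site {self.id}: residue list is empty")
        if self.source not in ("experimental", "model"):
            raise ValueError(f"binding site {self.id}: bad source {self.source!r}")
        if self.source == "model" and self.quality is None:
            raise ValueError(f"model site {self.id} lacks a quality score")
        self.residues = [(str(c), int(p), str(a)) for c, p, a in self.residues]


@dataclass(frozen=True)
class SimilarityEdge:
    """Weighted within-partition edge; similarity is an RFC probability for
    ligand pairs or a normalized Z for site pairs."""

    a: str
    b: str
    similarity: float
    kind: str = "ligand"

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop similarity edge on {self.a!r}")
        if self.similarity <= 0:
            raise ValueError(f"similarity must be positive, got {self.similarity}")
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"bad similarity kind {self.kind!r}")

    @property
    def distance(self) -> float:
        return similarity_to_distance(self.similarity)

    @property
    def key(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass(frozen=True)
class InteractionEdge:
    """Observed ligand-site interaction; always crosses the two partitions."""

    ligand_node: str
    site_node: str
    evidence: str = ""


@dataclass
class ClusterNode:
    """A condensed vertex: one or more mutually similar members."""

    id: str
    members: tuple[str, ...]
    partition: str

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError(f"cluster {self.id} has no members")
        if self.partition not in (LIGAND, SITE):
            raise ValueError(f"bad partition {self.partition!r}")
        self.members = tuple(self.members)


@dataclass
class Prediction:
    """One query-compound -> binding-site hit."""

    query_id: str
    site_id: str
    protein_id: str
    raw_score: float
    path: tuple[str, ...]
    score_norm: float | None = None
    global_z: float | None = None
    local_z: float | None = None
    classifier_prob: float | None = None
    classifier_label: bool | None = None

    def __post_init__(self) -> None:
        if self.path and (self.path[0] != self.query_id or self.path[-1] != self.site_id):
            raise ValueError(
                f"prediction path must run from {self.query_id} to {self.site_id}"
            )


class BipartiteNetwork:
    """The condensed ligand-cluster + site-cluster graph with integrated
    query compounds and modeled target sites.

    Invariants (checked by :meth:`validate`):

    * similarity edges never cross partitions; interaction edges always do;
    * the graph is simple (no self-loops, no parallel edges);
    * cluster member sets are disjoint and every member maps to one cluster.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.compounds: dict[str, Compound] = {}
        self.sites: dict[str, BindingSite] = {}
        self.member_to_cluster: dict[str, str] = {}

    # -- construction -------------------------------------------------

    def add_cluster(self, cluster: ClusterNode) -> None:
        if cluster.id in self.graph:
            raise NetworkInvariantError(f"duplicate node id {cluster.id!r}")
        for m in cluster.members:
            if m in self.member_to_cluster:
                raise NetworkInvariantError(
                    f"member {m!r} already assigned to {self.member_to_cluster[m]!r}"
                )
        self.graph.add_node(
            cluster.id,
            partition=cluster.partition,
            role="cluster",
            members=cluster.members,
        )
        for m in cluster.members:
            self.member_to_cluster[m] = cluster.id

    def add_query_node(self, query_id: str, unreachable: bool = False) -> None:
        self.graph.add_node(
            query_id, partition=LIGAND, role="query", members=(query_id,),
            unreachable=unreachable,
        )

    def add_target_site_node(self, site: BindingSite) -> None:
        self.graph.add_node(
            site.id, partition=SITE, role="target_site", members=(site.id,)
        )
        self.sites[site.id] = site

    def add_similarity_edge(self, a: str, b: str, similarity: float, kind: str) -> None:
        if kind not in SIMILARITY_KINDS:
            raise NetworkInvariantError(f"bad similarity kind {kind!r}")
        if a == b:
            raise NetworkInvariantError(f"self-loop on {a!r}")
        pa, pb = self.graph.nodes[a]["partition"], self.graph.nodes[b]["partition"]
        if pa != pb:
            raise NetworkInvariantError(
                f"similarity edge {a!r}-{b!r} crosses partitions {pa}/{pb}"
            )
        similarity = float(min(similarity, 1.0))
        self.graph.add_edge(
            a, b, kind=kind, similarity=similarity,
            distance=similarity_to_distance(similarity),
        )

    def add_interaction_edge(self, ligand_node: str, site_node: str,
                             evidence: str = "") -> None:
        pa = self.graph.nodes[ligand_node]["partition"]
        pb = self.graph.nodes[site_node]["partition"]
        if pa == pb:
            raise NetworkInvariantError(
                f"interaction edge {ligand_node!r}-{site_node!r} stays inside "
                f"partition {pa}"
            )
        if self.graph.has_edge(ligand_node, site_node):
            ev = self.graph.edges[ligand_node, site_node]["evidence"]
            if evidence and evidence not in ev:
                self.graph.edges[ligand_node, site_node]["evidence"] = ev + (evidence,)
        else:
            self.graph.add_edge(
                ligand_node, site_node, kind="interaction", similarity=1.0,
                distance=1.0, evidence=(evidence,) if evidence else (),
            )

    # -- views ---------------------------------------------------------

    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["role"] == role)

    @property
    def query_nodes(self) -> list[str]:
        return self.nodes_with_role("query")

    @property
    def target_site_nodes(self) -> list[str]:
        return self.nodes_with_role("target_site")

    def clusters(self, partition: str | None = None) -> list[ClusterNode]:
        out = []
        for n, d in self.graph.nodes(data=True):
            if d["role"] != "cluster":
                continue
            if partition is not None and d["partition"] != partition:
                continue
            out.append(ClusterNode(n, tuple(d["members"]), d["partition"]))
        return sorted(out, key=lambda c: c.id)

    def resolve_member(self, member_id: str) -> str | None:
        """Cluster (or standalone node) holding ``member_id``, if any."""
        if member_id in self.member_to_cluster:
            return self.member_to_cluster[member_id]
        if member_id in self.graph:
            return member_id
        return None

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for n, d in self.graph.nodes(data=True):
            if d["partition"] not in (LIGAND, SITE):
                raise NetworkInvariantError(f"node {n!r}: bad partition")
            for m in d.get("members", ()):
                if m in seen:
                    raise NetworkInvariantError(
                        f"member {m!r} in both {seen[m]!r} and {n!r}"
                    )
                seen[m] = n
        for a, b, d in self.graph.edges(data=True):
            if a == b:
                raise NetworkInvariantError(f"self-loop on {a!r}")
            cross = self.graph.nodes[a]["partition"] != self.graph.nodes[b]["partition"]
            if d["kind"] == "interaction" and not cross:
                raise NetworkInvariantError(
                    f"interaction edge {a!r}-{b!r} does not cross partitions"
                )
            if d["kind"] in SIMILARITY_KINDS and cross:
                raise NetworkInvariantError(
                    f"similarity edge {a!r}-{b!r} crosses partitions"
                )

    def summary(self) -> dict[str, int]:
        return {
            "vertices": self.graph.number_of_nodes(),
            "edges": self.graph.number_of_edges(),
            "ligand_clusters": len(self.clusters(LIGAND)),
            "site_clusters": len(self.clusters(SITE)),
            "queries": len(self.query_nodes),
            "target_sites": len(self.target_site_nodes),
        }


# ---------------------------------------------------------------------------
# tabular readers / writers


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})


def read_compound_table(
    path,
    format: str = "tsv",
    featurize: bool = True,
    on_bad_smiles: str = "warn",
) -> list[Compound]:
    """Read compounds from TSV (``id`` column plus optional ``smiles``,
    ``wqed``, descriptor columns), an SDF file, or a bare SMILES list.

    Malformed SMILES are record-level errors: the offending record is
    dropped with a warning naming its id (``on_bad_smiles='raise'`` makes
    them fatal).  Duplicate ids are always fatal.
    """
    if format == "tsv":
        records = _records_from_tsv(path)
    elif format == "sdf":
        records = _records_from_sdf(path)
    elif format == "smiles-list":
        records = _records_from_smiles_list(path)
    else:
        raise ValueError(f"unknown compound table format {format!r}")

    compounds: list[Compound] = []
    seen: set[str] = set()
    for rec in records:
        if rec["id"] in seen:
            raise ValueError(f"duplicate compound id {rec['id']!r}")
        seen.add(rec["id"])
        try:
            c = Compound(**rec)
            if featurize and c.smiles is not None:
                c.fingerprint = _chem.fingerprint_from_smiles(c.smiles)
                c.descriptors.update(_chem.descriptors_from_smiles(c.smiles))
            compounds.append(c)
        except ValueError as err:
            if on_bad_smiles == "raise":
                raise
            warnings.warn(f"compound {rec['id']!r} skipped: {err}")
    lengths = {len(c.fingerprint) for c in compounds if c.fingerprint is not None}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent fingerprint lengths {sorted(lengths)}")
    return compounds


def _records_from_tsv(path) -> list[dict]:
    df = _read_tsv(path)
    if "id" not in df.columns:
        raise ValueError("compound TSV needs an 'id' column")
    desc_cols = [c for c in df.columns if c in _chem.DESCRIPTOR_NAMES]
    recs = []
    for _, row in df.iterrows():
        rec: dict = {"id": str(row["id"])}
        if "smiles" in df.columns and pd.notna(row.get("smiles")):
            rec["smiles"] = str(row["smiles"])
        if "wqed" in df.columns and pd.notna(row.get("wqed")):
            rec["wqed"] = float(row["wqed"])
        if desc_cols:
            rec["descriptors"] = {
                c: float(row[c]) for c in desc_cols if pd.notna(row[c])
            }
        recs.append(rec)
    return recs


def _records_from_sdf(path) -> list[dict]:
    from rdkit import Chem

    recs = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            warnings.warn(f"SDF record {i} unparseable, skipped")
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") \
            else f"SDF{i:05d}"
        rec = {"id": cid, "smiles": Chem.MolToSmiles(mol)}
        if mol.HasProp("wqed"):
            rec["wqed"] = float(mol.GetProp("wqed"))
        recs.append(rec)
    return recs


def _records_from_smiles_list(path) -> list[dict]:
    recs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            cid = parts[1] if len(parts) > 1 else f"CMP{i + 1:05d}"
            recs.append({"id": cid, "smiles": parts[0]})
    return recs


def write_compound_table(compounds: Iterable[Compound], path) -> None:
    rows = []
    for c in compounds:
        row = {"id": c.id, "smiles": c.smiles, "wqed": c.wqed}
        row.update(c.descriptors)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _residues_to_str(residues: Sequence[tuple[str, int, str]]) -> str:
    return "|".join(f"{c}:{p}:{a}" for c, p, a in residues)


def _residues_from_str(s: str) -> list[tuple[str, int, str]]:
    out = []
    for tok in str(s).split("|"):
        chain, pos, aa = tok.split(":")
        out.append((chain, int(pos), aa))
    return out


def read_site_table(path) -> list[BindingSite]:
    """Binding sites from TSV (id, protein_id, residues, [source], [quality]);
    residues encoded ``chain:pos:aa|chain:pos:aa|...``."""
    df = _read_tsv(path)
    sites, seen = [], set()
    for _, row in df.iterrows():
        sid = str(row["id"])
        if sid in seen:
            raise ValueError(f"duplicate site id {sid!r}")
        seen.add(sid)
        quality = None
        if "quality" in df.columns and pd.notna(row.get("quality")):
            quality = float(row["quality"])
        sites.append(
            BindingSite(
                id=sid,
                protein_id=str(row["protein_id"]),
                residues=_residues_from_str(row["residues"]),
                source=str(row.get("source", "experimental"))
                if "source" in df.columns else "experimental",
                quality=quality,
            )
        )
    return sites


def write_site_table(sites: Iterable[BindingSite], path) -> None:
    pd.DataFrame(
        [
            {
                "id": s.id,
                "protein_id": s.protein_id,
                "residues": _residues_to_str(s.residues),
                "source": s.source,
                "quality": s.quality,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list[SimilarityEdge | InteractionEdge]:
    """Edges from TSV with columns (a, b, value, kind[, evidence]).

    Similarity rows are symmetrically deduplicated keeping the maximum
    value; self-loop rows are dropped with a warning; non-numeric values
    are fatal.  Interaction rows are kept as-is.
    """
    df = _read_tsv(path)
    for col in ("a", "b", "value", "kind"):
        if col not in df.columns:
            raise ValueError(f"edge list missing column {col!r}")
    best: dict[tuple[frozenset, str], float] = {}
    interactions: list[InteractionEdge] = []
    n_loops = 0
    for _, row in df.iterrows():
        a, b, kind = str(row["a"]), str(row["b"]), str(row["kind"])
        value = float(row["value"])  # non-numeric -> fatal via ValueError
        if a == b:
            n_loops += 1
            continue
        if kind == "interaction":
            ev = str(row["evidence"]) if "evidence" in df.columns and \
                pd.notna(row.get("evidence")) else ""
            interactions.append(InteractionEdge(a, b, ev))
        elif kind in SIMILARITY_KINDS:
            key = (frozenset((a, b)), kind)
            best[key] = max(best.get(key, 0.0), value)
        else:
            raise ValueError(f"unknown edge kind {kind!r}")
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop edge row(s)")
    sims = [
        SimilarityEdge(*sorted(key), similarity=v, kind=kind)
        for (key, kind), v in best.items()
    ]
    sims.sort(key=lambda e: (e.a, e.b, e.kind))
    return sims + interactions


def write_edge_list(edges: Iterable[SimilarityEdge | InteractionEdge], path) -> None:
    rows = []
    for e in edges:
        if isinstance(e, SimilarityEdge):
            rows.append({"a": e.a, "b": e.b, "value": e.similarity,
                         "kind": e.kind, "evidence": ""})
        else:
            rows.append({"a": e.ligand_node, "b": e.site_node, "value": 1.0,
                         "kind": "interaction", "evidence": e.evidence})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cluster_members(clusters: Iterable[ClusterNode], path) -> None:
    rows = [
        {"member_id": m, "cluster_id": c.id}
        for c in clusters
        for m in c.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


PREDICTION_COLUMNS = (
    "query_id", "protein_id", "site_id", "score", "protein_score",
    "global_z", "local_z", "classifier_prob", "classifier_label", "path",
)


def write_predictions(df: pd.DataFrame, path) -> None:
    cols = [c for c in PREDICTION_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return _read_tsv(path)


# ---------------------------------------------------------------------------
# network serialization


def write_network(network: BipartiteNetwork, path, format: str = "json") -> None:
    network.validate()
    path = Path(path)
    if format == "json":
        _write_network_json(network, path)
    elif format == "graphml":
        _write_network_graphml(network, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str | None = None) -> BipartiteNetwork:
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "json"
    net = _read_network_json(path) if format == "json" else _read_network_graphml(path)
    net.validate()
    return net


def _node_record(n: str, d: dict) -> dict:
    rec = {
        "id": n,
        "partition": d["partition"],
        "role": d["role"],
        "members": list(d.get("members", ())),
    }
    if d.get("unreachable"):
        rec["unreachable"] = True
    return rec


def _edge_record(a: str, b: str, d: dict) -> dict:
    rec = {"a": a, "b": b, "kind": d["kind"], "similarity": d["similarity"]}
    if d["kind"] == "interaction":
        rec["evidence"] = list(d.get("evidence", ()))
    return rec


def _write_network_json(network: BipartiteNetwork, path: Path) -> None:
    doc = {
        "format": "pocketpath-network",
        "version": 1,
        "nodes": [
            _node_record(n, d)
            for n, d in sorted(network.graph.nodes(data=True))
        ],
        "edges": [
            _edge_record(*sorted((a, b)), d)
            for a, b, d in sorted(network.graph.edges(data=True),
                                  key=lambda e: tuple(sorted(e[:2])))
        ],
        "compounds": [
            {"id": c.id, "smiles": c.smiles, "wqed": c.wqed,
             "descriptors": c.descriptors}
            for c in sorted(network.compounds.values(), key=lambda c: c.id)
        ],
        "sites": [
            {"id": s.id, "protein_id": s.protein_id,
             "residues": _residues_to_str(s.residues),
             "source": s.source, "quality": s.quality}
            for s in sorted(network.sites.values(), key=lambda s: s.id)
        ],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))


def _read_network_json(path: Path) -> BipartiteNetwork:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "pocketpath-network":
        raise ValueError(f"{path} is not a network JSON file")
    net = BipartiteNetwork()
    for rec in doc["nodes"]:
        net.graph.add_node(
            rec["id"], partition=rec["partition"], role=rec["role"],
            members=tuple(rec["members"]),
            **({"unreachable": True} if rec.get("unreachable") else {}),
        )
        if rec["role"] == "cluster":
            for m in rec["members"]:
                net.member_to_cluster[m] = rec["id"]
    for rec in doc["edges"]:
        if rec["kind"] == "interaction":
            net.graph.add_edge(
                rec["a"], rec["b"], kind="interaction", similarity=1.0,
                distance=1.0, evidence=tuple(rec.get("evidence", ())),
            )
        else:
            net.graph.add_edge(
                rec["a"], rec["b"], kind=rec["kind"],
                similarity=rec["similarity"],
                distance=similarity_to_distance(rec["similarity"]),
            )
    for rec in doc.get("compounds", []):
        net.compounds[rec["id"]] = Compound(
            id=rec["id"], smiles=rec.get("smiles"), wqed=rec.get("wqed"),
            descriptors=rec.get("descriptors") or {},
        )
    for rec in doc.get("sites", []):
        net.sites[rec["id"]] = BindingSite(
            id=rec["id"], protein_id=rec["protein_id"],
            residues=_residues_from_str(rec["residues"]),
            source=rec["source"], quality=rec.get("quality"),
        )
    return net


def _write_network_graphml(network: BipartiteNetwork, path: Path) -> None:
    # GraphML attributes must be scalars: join members / evidence with '|'
    g = nx.Graph()
    for n, d in network.graph.nodes(data=True):
        g.add_node(n, partition=d["partition"], role=d["role"],
                   members="|".join(d.get("members", ())),
                   unreachable=bool(d.get("unreachable", False)))
    for a, b, d in network.graph.edges(data=True):
        g.add_edge(a, b, kind=d["kind"], similarity=float(d["similarity"]),
                   evidence="|".join(d.get("evidence", ())))
    nx.write_graphml(g, path)


def _read_network_graphml(path: Path) -> BipartiteNetwork:
    g = nx.read_graphml(path)
    net = BipartiteNetwork()
    for n, d in g.nodes(data=True):
        members = tuple(d["members"].split("|")) if d.get("members") else ()
        net.graph.add_node(
            n, partition=d["partition"], role=d["role"], members=members,
            **({"unreachable": True} if d.get("unreachable") else {}),
        )
        if d["role"] == "cluster":
            for m in members:
                net.member_to_cluster[m] = n
    for a, b, d in g.edges(data=True):
        if d["kind"] == "interaction":
            ev = tuple(d["evidence"].split("|")) if d.get("evidence") else ()
            net.graph.add_edge(a, b, kind="interaction", similarity=1.0,
                               distance=1.0, evidence=ev)
        else:
            net.graph.add_edge(a, b, kind=d["kind"],
                               similarity=float(d["similarity"]),
                               distance=similarity_to_distance(d["similarity"]))
    return net
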