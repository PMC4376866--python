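import numpy as np
import pytest

from pocketpath.model_io import BindingSite, BipartiteNetwork, ClusterNode, Compound
from pocketpath.similarity import featurize_compound


SMILES = {
    "ETH": "CCO",
    "BNZ": "c1ccccc1",
    "TOL": "Cc1ccccc1",
    "PYR": "c1ccncc1",
    "PHE": "Oc1ccccc1",
    "ANI": "Nc1ccccc1",
}


@pytest.fixture(scope="session")
def compounds() -> dict[str, Compound]:
    """A handful of featurized compounds keyed by id."""
    out = {}
    for cid, smi in SMILES.items():
        c = Compound(id=cid, smiles=smi, wqed=0.5)
        featurize_compound(c)
        out[cid] = c
    return out


def make_site(sid: str, protein: str = "P1", n_res: int = 8,
              start: int = 1, **kw) -> BindingSite:
    residues = [("A", start + i, "GLY") for i in range(n_res)]
    return BindingSite(id=sid, protein_id=protein, residues=residues, **kw)


@pytest.fixture
def toy_network() -> BipartiteNetwork:
    """Two ligand clusters, two site clusters, one interaction edge,
    one modeled target site: the smallest network with a full
    query -> ligand -> site -> target path."""
    net = BipartiteNetwork()
    net.add_cluster(ClusterNode("LC0", ("l1", "l2"), "ligand"))
    net.add_cluster(ClusterNode("LC1", ("l3",), "ligand"))
    net.add_cluster(ClusterNode("SC0", ("s1", "s2"), "site"))
    net.add_cluster(ClusterNode("SC1", ("s3",), "site"))
    net.add_similarity_edge("LC0", "LC1", 0.5, kind="ligand")
    net.add_similarity_edge("SC0", "SC1", 0.8, kind="site")
    net.add_interaction_edge("LC0", "SC0", evidence="CPLX1")
    net.sites["s1"] = make_site("s1", "KP1")
    net.sites["s2"] = make_site("s2", "KP2")
    net.sites["s3"] = make_site("s3", "KP3")
    target = make_site("T1", "HP1", source="model", quality=1.5)
    net.add_target_site_node(target)
    net.add_similarity_edge("T1", "SC0", 1.0, kind="site_model")
    net.add_query_node("Q1")
    net.add_similarity_edge("Q1", "LC0", 1.0, kind="ligand")
    net.validate()
    return net
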