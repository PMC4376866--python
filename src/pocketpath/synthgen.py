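"""Synthetic universe generator.

Emits a complete, internally consistent set of pipeline inputs —
compounds, binding sites, pairwise similarity tables, observed
interactions, model-site comparison tables and truth labels — with the
statistical structure the method assumes: similar pockets bind similar
ligands.  Compounds are organized into scaffold families and binding
sites into pocket classes; each pocket class is bound by one or two
scaffolds, and the planted (query, protein) truth pairs are exactly the
scaffold/class co-memberships.

Generation is a pure function of the configuration (one seeded generator,
no global state), so every stage of the pipeline and its tests run
offline and reproducibly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import (
    BindingSite,
    Compound,
    write_compound_table,
    write_site_table,
    write_edge_list,
    SimilarityEdge,
)

log = logging.getLogger(__name__)

# scaffold cores; cycled with growing alkyl tails if more are requested
_CORES = (
    "c1ccccc1",
    "c1ccncc1",
    "C1CCCCC1",
    "c1ccc2ccccc2c1",
    "C1CCNCC1",
    "c1ccsc1",
    "c1ccoc1",
    "C1CCOC1",
    "c1cnccn1",
    "C1CCCC1",
)
_SUBSTITUENT_SUFFIX = ("", "O", "N")


@dataclass
class SynthConfig:
    """Knobs of the synthetic universe.

    ``cross_class_noise`` is the probability that a cross-scaffold ligand
    pair, a cross-class site pair or a cross-class model-site comparison
    is drawn from the *within*-group distribution instead — i.e. the rate
    of confusing, spurious similarity signal.  ``similarity_noise_sd`` is
    Gaussian jitter added to every ligand-pair similarity.
    """

    n_scaffolds: int = 8
    ligands_per_scaffold: int = 6
    n_pocket_classes: int = 10
    sites_per_class: int = 5
    cross_class_noise: float = 0.05
    similarity_noise_sd: float = 0.05
    p_interaction_within_class: float = 0.9
    n_queries: int = 48
    seed: int = 7
    # secondary knobs, rarely touched
    n_decoys: int = 8                  # low-drug-likeness compounds, no truth role
    targets_per_class: int = 2         # modeled proteins per pocket class
    # heterogeneity of the universe (all paper-motivated):
    # most pocket classes are selective (bound by 1-2 scaffolds); a minority
    # are promiscuous pockets bound by many chemotypes
    scaffolds_per_class_choices: tuple[int, ...] = (1, 1, 2, 2, 4)
    # per-target model quality: each modeled site has its own comparison
    # Z level (well- vs poorly-modeled targets), jittered per known site
    target_z_range: tuple[float, float] = (3.0, 6.5)
    target_z_jitter: float = 0.3
    # per-query promiscuity: a multiplicative factor on all of a query's
    # pair probabilities (sticky vs clean compounds)
    query_strength_range: tuple[float, float] = (0.9, 1.12)

    def __post_init__(self) -> None:
        for name in ("n_scaffolds", "ligands_per_scaffold", "n_pocket_classes",
                     "sites_per_class", "n_queries", "targets_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.cross_class_noise < 1.0):
            raise ValueError("cross_class_noise must lie in [0, 1)")
        if not (0.0 < self.p_interaction_within_class <= 1.0):
            raise ValueError("p_interaction_within_class must lie in (0, 1]")
        if self.similarity_noise_sd < 0:
            raise ValueError("similarity_noise_sd must be >= 0")
        if self.n_scaffolds == 1 and self.n_pocket_classes == 1:
            warnings.warn("1 scaffold x 1 pocket class: universe is unseparable")


@dataclass
class SyntheticUniverse:
    """Everything the pipeline consumes, as in-memory objects."""

    config: SynthConfig
    compounds: list[Compound]
    queries: list[Compound]
    sites: list[BindingSite]
    model_sites: list[BindingSite]
    ligand_sim: pd.DataFrame        # a, b, value, kind
    site_sim: pd.DataFrame          # a, b, zscore
    query_sim: pd.DataFrame         # query_id, compound_id, prob
    interactions: pd.DataFrame      # ligand_id, site_id, evidence
    comparisons: pd.DataFrame       # model_site, known_site, seq_id_site,
                                    # struct_id_site, probis_z
    truth: pd.DataFrame             # query_id, protein_id, label
    scaffold_of: dict[str, int]
    class_of_protein: dict[str, int]
    scaffolds_of_class: dict[int, tuple[int, ...]]

    def write(self, outdir) -> dict[str, Path]:
        """Emit every table as the TSV dialect the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_compound_table(self.compounds, outdir / "compounds.tsv")
        write_compound_table(self.queries, outdir / "queries.tsv")
        write_site_table(self.sites, outdir / "sites.tsv")
        write_site_table(self.model_sites, outdir / "model_sites.tsv")
        self.ligand_sim.to_csv(outdir / "ligand_sim.tsv", sep="\t", index=False)
        self.site_sim.to_csv(outdir / "site_sim.tsv", sep="\t", index=False)
        self.query_sim.to_csv(outdir / "query_sim.tsv", sep="\t", index=False)
        self.interactions.to_csv(outdir / "interactions.tsv", sep="\t",
                                 index=False)
        self.comparisons.to_csv(outdir / "comparisons.tsv", sep="\t",
                                index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for name in ("compounds", "queries", "sites", "model_sites",
                     "ligand_sim", "site_sim", "query_sim", "interactions",
                     "comparisons", "truth"):
            paths[name] = outdir / f"{name}.tsv"
        return paths


def _scaffold_smiles(scaffold: int, variant: int) -> str:
    core = _CORES[scaffold % len(_CORES)]
    extra = "C" * (scaffold // len(_CORES))
    chain = "C" * (variant // len(_SUBSTITUENT_SUFFIX) + 1)
    suffix = _SUBSTITUENT_SUFFIX[variant % len(_SUBSTITUENT_SUFFIX)]
    return f"{suffix}{chain}{extra}{core}"


def _pair_similarity(rng, same_group: bool, noise: float, jitter_sd: float) -> float:
    # confusable cross-group pairs sit near the decision boundary (false
    # similarity calls are borderline, not confidently high)
    confusable = (not same_group) and rng.random() < noise
    if same_group:
        v = rng.beta(8.0, 2.0)          # centred near 0.8
    elif confusable:
        v = rng.beta(5.0, 5.0)          # centred near 0.5
    else:
        v = rng.beta(2.0, 8.0)          # centred near 0.2
    v += rng.normal(0.0, jitter_sd)
    return float(np.clip(v, 0.01, 1.0))


def _pair_z(rng, same_group: bool, noise: float) -> float:
    confusable = (not same_group) and rng.random() < noise
    if same_group:
        return float(rng.normal(4.0, 1.0))
    if confusable:
        return float(rng.normal(2.5, 1.0))  # just above the edge threshold
    return float(rng.normal(0.0, 1.0))


def generate_universe(config: SynthConfig | None = None) -> SyntheticUniverse:
    """Generate the whole synthetic universe from one seeded generator."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    noise = cfg.cross_class_noise

    # -- compounds: scaffold families plus low-drug-likeness decoys -----
    compounds: list[Compound] = []
    scaffold_of: dict[str, int] = {}
    for s in range(cfg.n_scaffolds):
        for i in range(cfg.ligands_per_scaffold):
            cid = f"L{s:02d}_{i:02d}"
            compounds.append(
                Compound(id=cid, smiles=_scaffold_smiles(s, i),
                         wqed=float(rng.uniform(0.36, 0.95)))
            )
            scaffold_of[cid] = s
    for d in range(cfg.n_decoys):
        compounds.append(
            Compound(id=f"X{d:02d}", smiles=_scaffold_smiles(d, d + 7),
                     wqed=float(rng.uniform(0.05, 0.30)))
        )

    network_ids = [c.id for c in compounds if c.id.startswith("L")]

    # -- ligand pairwise similarities (RFC-probability scale) -----------
    lig_rows = []
    for i, a in enumerate(network_ids):
        for b in network_ids[i + 1:]:
            same = scaffold_of[a] == scaffold_of[b]
            lig_rows.append(
                {"a": a, "b": b,
                 "value": _pair_similarity(rng, same, noise,
                                           cfg.similarity_noise_sd),
                 "kind": "ligand"}
            )
    # decoys: uniformly weak similarity to everything
    for c in compounds:
        if not c.id.startswith("X"):
            continue
        for b in network_ids:
            lig_rows.append({"a": c.id, "b": b,
                             "value": float(np.clip(rng.beta(2, 8), 0.01, 1)),
                             "kind": "ligand"})
    ligand_sim = pd.DataFrame(lig_rows)

    # -- binding sites per pocket class ---------------------------------
    sites: list[BindingSite] = []
    class_of_site: dict[str, int] = {}
    for c in range(cfg.n_pocket_classes):
        pool = [("A", c * 100 + j, "GLY") for j in range(20)]
        for i in range(cfg.sites_per_class):
            n_res = int(rng.integers(8, 12))
            idx = rng.choice(len(pool), size=n_res, replace=False)
            sid = f"S{c:02d}_{i:02d}"
            sites.append(
                BindingSite(id=sid, protein_id=f"KP{c:02d}_{i:02d}",
                            residues=[pool[j] for j in sorted(idx)])
            )
            class_of_site[sid] = c

    site_rows = []
    site_ids = [s.id for s in sites]
    for i, a in enumerate(site_ids):
        for b in site_ids[i + 1:]:
            same = class_of_site[a] == class_of_site[b]
            site_rows.append({"a": a, "b": b,
                              "zscore": _pair_z(rng, same, noise)})
    site_sim = pd.DataFrame(site_rows)

    # -- interactions: each pocket class bound by 1-2 scaffolds ---------
    scaffolds_of_class: dict[int, tuple[int, ...]] = {}
    inter_rows = []
    n_cplx = 0
    for c in range(cfg.n_pocket_classes):
        k = min(int(rng.choice(cfg.scaffolds_per_class_choices)),
                cfg.n_scaffolds)
        chosen = tuple(sorted(rng.choice(cfg.n_scaffolds, size=k,
                                         replace=False).tolist()))
        scaffolds_of_class[c] = chosen
        for s in chosen:
            for i in range(cfg.ligands_per_scaffold):
                for j in range(cfg.sites_per_class):
                    if rng.random() < cfg.p_interaction_within_class:
                        n_cplx += 1
                        inter_rows.append(
                            {"ligand_id": f"L{s:02d}_{i:02d}",
                             "site_id": f"S{c:02d}_{j:02d}",
                             "evidence": f"CPLX{n_cplx:05d}"}
                        )
    interactions = pd.DataFrame(inter_rows)

    # -- modeled target proteins and their comparison table -------------
    model_sites: list[BindingSite] = []
    class_of_protein: dict[str, int] = {}
    for c in range(cfg.n_pocket_classes):
        pool = [("A", c * 100 + j, "GLY") for j in range(20)]
        for t in range(cfg.targets_per_class):
            pid = f"HP{c:02d}_{t}"
            class_of_protein[pid] = c
            n_res = int(rng.integers(7, 13))
            idx = rng.choice(len(pool), size=n_res, replace=False)
            model_sites.append(
                BindingSite(id=f"MS{c:02d}_{t}", protein_id=pid,
                            residues=[pool[j] for j in sorted(idx)],
                            source="model",
                            quality=float(rng.uniform(1.2, 2.0)))
            )

    cmp_rows = []
    for ms in model_sites:
        mc = class_of_protein[ms.protein_id]
        # per-target modeling quality: the comparison Z level of this site
        z_level = float(rng.uniform(*cfg.target_z_range))
        for sid in site_ids:
            same = class_of_site[sid] == mc
            confus = (not same) and rng.random() < noise
            if same:
                seq_id = float(rng.uniform(55, 95))
                struct_id = float(rng.uniform(55, 95))
                z = float(z_level + rng.normal(0.0, cfg.target_z_jitter))
            elif confus:
                seq_id = float(rng.uniform(35, 60))
                struct_id = float(rng.uniform(35, 60))
                z = float(rng.normal(2.5, 1.0))
            else:
                seq_id = float(rng.uniform(5, 35))
                struct_id = float(rng.uniform(5, 35))
                # centred so the tail mass above the model-link cut (z > 1)
                # matches the cross-class tail of the site table at its own
                # cut (z > 2): ~2.3% spurious links in either context
                z = float(rng.normal(-1.0, 1.0))
            cmp_rows.append({"model_site": ms.id, "known_site": sid,
                             "seq_id_site": seq_id, "struct_id_site": struct_id,
                             "probis_z": z})
    comparisons = pd.DataFrame(cmp_rows)

    # -- queries and their emulated pair-classifier probabilities -------
    queries: list[Compound] = []
    q_rows = []
    for q in range(cfg.n_queries):
        s = q % cfg.n_scaffolds
        qid = f"Q{q:02d}"
        queries.append(
            Compound(id=qid,
                     smiles=_scaffold_smiles(s, cfg.ligands_per_scaffold + q),
                     wqed=float(rng.uniform(0.36, 0.95)))
        )
        scaffold_of[qid] = s
        # per-query promiscuity factor scaling every pair probability
        strength = float(rng.uniform(*cfg.query_strength_range))
        for b in network_ids:
            same = scaffold_of[b] == s
            prob = strength * _pair_similarity(rng, same, noise,
                                               cfg.similarity_noise_sd)
            q_rows.append({"query_id": qid, "compound_id": b,
                           "prob": float(np.clip(prob, 0.01, 1.0))})
    query_sim = pd.DataFrame(q_rows)

    # -- planted truth: scaffold / pocket-class co-membership -----------
    truth_rows = []
    for qc in queries:
        s = scaffold_of[qc.id]
        for ms in model_sites:
            c = class_of_protein[ms.protein_id]
            label = int(s in scaffolds_of_class[c])
            truth_rows.append({"query_id": qc.id, "protein_id": ms.protein_id,
                               "label": label})
    truth = pd.DataFrame(truth_rows).drop_duplicates() \
        .sort_values(["query_id", "protein_id"]).reset_index(drop=True)

    log.info("synthetic universe: %d compounds (+%d decoys), %d sites, "
             "%d model sites, %d interactions, %d truth pairs (%d positive)",
             len(network_ids), cfg.n_decoys, len(sites), len(model_sites),
             len(interactions), len(truth), int(truth["label"].sum()))
    return SyntheticUniverse(
        config=cfg, compounds=compounds, queries=queries, sites=sites,
        model_sites=model_sites, ligand_sim=ligand_sim, site_sim=site_sim,
        query_sim=query_sim, interactions=interactions,
        comparisons=comparisons, truth=truth, scaffold_of=scaffold_of,
        class_of_protein=class_of_protein,
        scaffolds_of_class=scaffolds_of_class,
    )


def config_to_dict(cfg: SynthConfig) -> dict:
    return asdict(cfg)
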