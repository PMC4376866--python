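"""End-to-end pipeline stages with file-based handoff.

Each stage is a pure function ``stage_*(workdir, config)`` that reads the
artifacts of earlier stages from ``workdir``, writes its own artifacts
there, and drops a manifest (input checksums, configuration, seed,
package version) so any run can be replayed.  The command-line interface
is a thin wrapper over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .model_io import (
    read_compound_table,
    read_site_table,
    read_network,
    write_network,
    write_predictions,
    read_predictions,
)
from .similarity import (
    filter_druglike,
    ligand_edges_from_table,
    site_edges_from_table,
)
from .assemble import (
    assemble_network,
    build_subnetwork,
    integrate_query_compounds,
    integrate_target_sites,
    link_interactions,
)
from .predict import predict_all
from .classify import (
    CVReport,
    oof_probabilities,
    save_model,
    single_score_cv_auc,
    train_meta_classifier,
    train_pair_classifier,
)
from .benchmark import evaluate, ranking_auc
from .synthgen import SynthConfig, generate_universe

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Configuration for the whole stage chain (YAML-serializable)."""

    seed: int = 7
    # synthetic universe (stage: simulate)
    synth: dict = field(default_factory=dict)
    # network construction (stage: build)
    wqed_threshold: float = 0.35
    ligand_edge_threshold: float = 0.5
    site_zmin: float = 2.0
    cluster_mode: str = "clique"
    kcore_k: int = 2
    # integration (stage: integrate)
    model_quality_min: float = 1.1
    identity_min_pct: float = 40.0
    redundancy_pct: float = 80.0
    min_site_residues: int = 6
    model_zmin: float = 1.0
    query_edge_threshold: float = 0.5
    # prediction (stage: predict)
    d_max: float = 10.0
    normalize: str = "minmax"
    local_scope: str = "site"
    # classifiers (stages: train, benchmark)
    forest_params: dict = field(default_factory=dict)
    cv_folds: int = 10
    classify_threshold: float = 0.5

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def synth_config(self) -> SynthConfig:
        known = {f.name for f in dataclasses.fields(SynthConfig)}
        unknown = set(self.synth) - known
        if unknown:
            raise ConfigError(f"unknown synth key(s): {sorted(unknown)}")
        kwargs = dict(self.synth)
        kwargs.setdefault("seed", self.seed)
        return SynthConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(workdir: Path, stage: str, cfg: PipelineConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    (workdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )


def _require(workdir: Path, name: str, produced_by: str) -> Path:
    p = workdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {name!r}; run the {produced_by!r} stage first"
        )
    return p


# ---------------------------------------------------------------------------
# stages


def stage_simulate(workdir, cfg: PipelineConfig) -> dict:
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    universe = generate_universe(cfg.synth_config())
    paths = universe.write(workdir)
    _write_manifest(workdir, "simulate", cfg, [], list(paths.values()))
    return {"files": sorted(p.name for p in paths.values())}


def stage_build(workdir, cfg: PipelineConfig) -> dict:
    workdir = Path(workdir)
    compounds = read_compound_table(_require(workdir, "compounds.tsv", "simulate"))
    druglike = filter_druglike(compounds, threshold=cfg.wqed_threshold)
    keep_ids = {c.id for c in druglike}

    lig_df = pd.read_csv(_require(workdir, "ligand_sim.tsv", "simulate"), sep="\t")
    lig_pairs = [
        (str(r.a), str(r.b), float(r.value))
        for r in lig_df.itertuples()
        if r.value >= cfg.ligand_edge_threshold
        and str(r.a) in keep_ids and str(r.b) in keep_ids
    ]
    ligand_edges = ligand_edges_from_table(lig_pairs)

    sites = read_site_table(_require(workdir, "sites.tsv", "simulate"))
    site_df = pd.read_csv(_require(workdir, "site_sim.tsv", "simulate"), sep="\t")
    site_edges = site_edges_from_table(
        [(str(r.a), str(r.b), float(r.zscore)) for r in site_df.itertuples()],
        zmin=cfg.site_zmin,
    )

    lc, lg = build_subnetwork(ligand_edges, "ligand", nodes=sorted(keep_ids),
                              mode=cfg.cluster_mode, k=cfg.kcore_k)
    sc, sg = build_subnetwork(site_edges, "site", nodes=[s.id for s in sites],
                              mode=cfg.cluster_mode, k=cfg.kcore_k)
    net = assemble_network(lc, lg, sc, sg, compounds=druglike, sites=sites)

    inter = pd.read_csv(_require(workdir, "interactions.tsv", "simulate"), sep="\t")
    skipped = link_interactions(
        net, [(str(r.ligand_id), str(r.site_id), str(r.evidence))
              for r in inter.itertuples()]
    )
    write_network(net, workdir / "network.json")
    _write_manifest(workdir, "build", cfg,
                    [workdir / n for n in ("compounds.tsv", "ligand_sim.tsv",
                                           "sites.tsv", "site_sim.tsv",
                                           "interactions.tsv")],
                    [workdir / "network.json"])
    summary = net.summary()
    summary["interactions_skipped"] = skipped
    summary["compounds_filtered_out"] = len(compounds) - len(druglike)
    return summary


def stage_integrate(workdir, cfg: PipelineConfig) -> dict:
    workdir = Path(workdir)
    net = read_network(_require(workdir, "network.json", "build"))
    model_sites = read_site_table(_require(workdir, "model_sites.tsv", "simulate"))
    comparisons = pd.read_csv(_require(workdir, "comparisons.tsv", "simulate"),
                              sep="\t")
    report = integrate_target_sites(
        net, model_sites, comparisons,
        quality_min=cfg.model_quality_min, identity_min=cfg.identity_min_pct,
        redundancy_pct=cfg.redundancy_pct, min_residues=cfg.min_site_residues,
        zmin=cfg.model_zmin,
    )

    queries = read_compound_table(_require(workdir, "queries.tsv", "simulate"))
    qsim = pd.read_csv(_require(workdir, "query_sim.tsv", "simulate"), sep="\t")
    table = {
        (str(r.query_id), str(r.compound_id)): float(r.prob)
        for r in qsim.itertuples()
    }
    unreachable = integrate_query_compounds(
        net, queries, table, edge_threshold=cfg.query_edge_threshold
    )
    write_network(net, workdir / "network_full.json")
    _write_manifest(workdir, "integrate", cfg,
                    [workdir / n for n in ("network.json", "model_sites.tsv",
                                           "comparisons.tsv", "queries.tsv",
                                           "query_sim.tsv")],
                    [workdir / "network_full.json"])
    out = net.summary()
    out.update({
        "model_sites_in": report.n_input,
        "model_sites_kept": report.n_after_redundancy,
        "model_edges_added": report.n_edges_added,
        "unreachable_queries": len(unreachable),
    })
    return out


def stage_train(workdir, cfg: PipelineConfig) -> dict:
    """Train the compound-pair classifier on the universe's reference
    similarity calls (pairs labeled by the similarity table)."""
    workdir = Path(workdir)
    compounds = read_compound_table(_require(workdir, "compounds.tsv", "simulate"))
    by_id = {c.id: c for c in compounds}
    lig_df = pd.read_csv(_require(workdir, "ligand_sim.tsv", "simulate"), sep="\t")
    pairs = [
        (by_id[str(r.a)], by_id[str(r.b)],
         int(r.value >= cfg.ligand_edge_threshold))
        for r in lig_df.itertuples()
        if str(r.a) in by_id and str(r.b) in by_id
    ]
    model = train_pair_classifier(pairs, params=cfg.forest_params or None,
                                  seed=cfg.seed)
    save_model(model, workdir / "pair_model.joblib")
    _write_manifest(workdir, "train", cfg,
                    [workdir / "compounds.tsv", workdir / "ligand_sim.tsv"],
                    [workdir / "pair_model.joblib"])
    return {"n_pairs": len(pairs), "cv_accuracy": model.cv_accuracy}


def stage_predict(workdir, cfg: PipelineConfig) -> dict:
    workdir = Path(workdir)
    net = read_network(_require(workdir, "network_full.json", "integrate"))
    preds = predict_all(net, d_max=cfg.d_max, normalize=cfg.normalize,
                        local_scope=cfg.local_scope)
    write_predictions(preds, workdir / "predictions.tsv")
    _write_manifest(workdir, "predict", cfg, [workdir / "network_full.json"],
                    [workdir / "predictions.tsv"])
    return {"n_predictions": len(preds),
            "n_queries_with_hits": preds["query_id"].nunique() if len(preds) else 0}


def label_predictions(preds: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """One labeled row per (query, protein): the best-scoring site row of
    each predicted pair, joined with its truth label.  Truth pairs never
    predicted are absent (they count as misses downstream)."""
    best = (
        preds.sort_values(["query_id", "protein_id", "score"],
                          ascending=[True, True, False])
        .groupby(["query_id", "protein_id"], as_index=False)
        .first()
    )
    merged = best.merge(truth, on=["query_id", "protein_id"], how="inner")
    return merged


def stage_benchmark(workdir, cfg: PipelineConfig) -> dict:
    workdir = Path(workdir)
    preds = read_predictions(_require(workdir, "predictions.tsv", "predict"))
    truth = pd.read_csv(_require(workdir, "truth.tsv", "simulate"), sep="\t")
    labeled = label_predictions(preds, truth)

    params = cfg.forest_params or None
    anon = train_meta_classifier(labeled, use_compound_id=False, params=params,
                                 seed=cfg.seed, cv_folds=cfg.cv_folds)
    aware = train_meta_classifier(labeled, use_compound_id=True, params=params,
                                  seed=cfg.seed, cv_folds=cfg.cv_folds)

    # honest calls from out-of-fold probabilities of the anonymous model
    prob = oof_probabilities(labeled, use_compound_id=False, params=params,
                             seed=cfg.seed, cv_folds=cfg.cv_folds)
    called = labeled.copy()
    called["classifier_prob"] = prob
    called["classifier_label"] = prob >= cfg.classify_threshold
    metrics_eval = evaluate(called, truth, score_col="classifier_prob",
                            label_col="classifier_label")

    single_auc = ranking_auc(preds, truth, score_col="score")
    # Table-1-style comparators: fold-mean AUC of each raw score on the
    # same stratified folds as the classifier CV
    single_cv = {
        col: single_score_cv_auc(labeled, col, seed=cfg.seed,
                                 cv_folds=cfg.cv_folds)
        for col in ("score", "global_z", "local_z")
    }

    metrics = {
        "single_score_auc": single_auc,
        "single_score_cv": {k: {"auc_mean": v[0], "auc_sd": v[1]}
                            for k, v in single_cv.items()},
        "best_single_cv_auc": max(v[0] for v in single_cv.values()),
        "anonymous_cv": anon.cv.as_dict() if anon.cv else None,
        "id_aware_cv": aware.cv.as_dict() if aware.cv else None,
        "classifier_precision": metrics_eval["precision"],
        "classifier_recall": metrics_eval["recall"],
        "classifier_auc": metrics_eval["auc"],
        "n_labeled_pairs": int(len(labeled)),
        "n_positive": int(labeled["label"].sum()),
    }
    (workdir / "metrics.json").write_text(
        json.dumps(metrics, indent=1, sort_keys=True)
    )
    pd.DataFrame(metrics_eval["roc_points"], columns=["fpr", "tpr"]) \
        .to_csv(workdir / "roc.tsv", sep="\t", index=False)
    pd.DataFrame(metrics_eval["enrichment_curve"],
                 columns=["frac_examined", "frac_recovered"]) \
        .to_csv(workdir / "enrichment.tsv", sep="\t", index=False)
    _write_manifest(workdir, "benchmark", cfg,
                    [workdir / "predictions.tsv", workdir / "truth.tsv"],
                    [workdir / n for n in ("metrics.json", "roc.tsv",
                                           "enrichment.tsv")])
    return metrics


STAGES = {
    "simulate": stage_simulate,
    "build": stage_build,
    "integrate": stage_integrate,
    "train": stage_train,
    "predict": stage_predict,
    "benchmark": stage_benchmark,
}


def run_stage(name: str, workdir, cfg: PipelineConfig) -> dict:
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    log.info("running stage %s in %s", name, workdir)
    return STAGES[name](workdir, cfg)


def run_all(workdir, cfg: PipelineConfig,
            stages: tuple[str, ...] = ("simulate", "build", "integrate",
                                       "train", "predict", "benchmark")) -> dict:
    out = {}
    for name in stages:
        out[name] = run_stage(name, workdir, cfg)
    return out
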