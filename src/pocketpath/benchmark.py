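"""Benchmark protocol: positive / negative set construction, the
miss-annotation screen, identity-edge exclusion, and the evaluation
battery (precision, recall, ROC/AUC, enrichment curves).

Positives are observed (drug, target) annotations; negatives are sampled
uniformly from never-annotated combinations.  Because a sampled negative
may simply be an undiscovered interaction, a screen flags negatives whose
drug has a similar compound annotated against the same target.  To avoid
rewarding trivial self-matches, edges between a benchmark entity and an
identical network entity are removed before prediction.
"""

from __future__ import annotations

import logging
import random
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from .model_io import LIGAND, SITE, BipartiteNetwork

log = logging.getLogger(__name__)

Pair = tuple[str, str]


def build_positive_set(
    interaction_records: Iterable[tuple[str, str, str]],
    drug_whitelist: Iterable[str] | None = None,
) -> list[Pair]:
    """Deduplicated (drug, target) pairs, optionally restricted to a
    whitelist of drugs."""
    wl = set(drug_whitelist) if drug_whitelist is not None else None
    pairs = {
        (drug, target)
        for drug, target, *_ in interaction_records
        if wl is None or drug in wl
    }
    return sorted(pairs)


def build_negative_set(
    universe: Iterable[Pair],
    positives: Iterable[Pair],
    n: int,
    seed: int,
) -> list[Pair]:
    """Sample ``n`` never-annotated (drug, target) pairs uniformly without
    replacement; reproducible by seed."""
    pos = set(positives)
    candidates = sorted(set(universe) - pos)
    if n > len(candidates):
        raise ValueError(
            f"cannot sample {n} negatives from {len(candidates)} unannotated pairs"
        )
    rng = random.Random(seed)
    return sorted(rng.sample(candidates, n))


def screen_negatives(
    negatives: Sequence[Pair],
    similar_compounds: Callable[[str], Iterable[str]] | Mapping[str, Iterable[str]],
    interactions: Iterable[Pair],
) -> list[Pair]:
    """Flag negatives that are likely miss-annotated true interactions.

    A negative (drug, target) is flagged when some compound similar to the
    drug has an annotated interaction with that same target.
    ``similar_compounds`` maps a drug to its similar compounds (same
    notion of "similar" as network edge creation).
    """
    if isinstance(similar_compounds, Mapping):
        table = similar_compounds

        def lookup(drug: str) -> Iterable[str]:
            return table.get(drug, ())
    else:
        lookup = similar_compounds
    annotated = set(interactions)
    flagged = [
        (drug, target)
        for drug, target in negatives
        if any((sim, target) in annotated for sim in lookup(drug))
    ]
    log.info("miss-annotation screen: %d / %d negatives flagged",
             len(flagged), len(negatives))
    return flagged


def exclude_identity_links(
    network: BipartiteNetwork,
    benchmark_ligands: Iterable[str] = (),
    benchmark_sites: Iterable[str] = (),
    identity_similarity: float = 1.0,
) -> int:
    """Remove similarity edges of weight 1.0 between a benchmark entity and
    the network, preventing a benchmark compound/site from trivially
    matching its identical copy.  Returns the number of edges removed."""
    targets = set(benchmark_ligands) | set(benchmark_sites)
    to_drop = []
    for a, b, d in network.graph.edges(data=True):
        if d["kind"] == "interaction":
            continue
        if (a in targets or b in targets) and \
                d["similarity"] >= identity_similarity:
            to_drop.append((a, b))
    network.graph.remove_edges_from(to_drop)
    log.info("identity exclusion: removed %d edge(s)", len(to_drop))
    return len(to_drop)


# ---------------------------------------------------------------------------
# evaluation


def _align_scores(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    score_col: str,
    higher_is_better: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """One (label, score) per truth pair at protein granularity; truth
    pairs the predictor never reached get the worst observed score."""
    best: dict[Pair, float] = {}
    sign = 1.0 if higher_is_better else -1.0
    for _, r in predictions.iterrows():
        key = (str(r["query_id"]), str(r["protein_id"]))
        v = sign * float(r[score_col])
        if key not in best or v > best[key]:
            best[key] = v
    floor = min(best.values()) - 1.0 if best else -1.0
    y_true, y_score = [], []
    for _, r in truth.iterrows():
        key = (str(r["query_id"]), str(r["protein_id"]))
        y_true.append(int(r["label"]))
        y_score.append(best.get(key, floor))
    return np.asarray(y_true), np.asarray(y_score)


def evaluate(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    score_col: str = "score",
    higher_is_better: bool = True,
    label_col: str | None = None,
) -> dict:
    """Score a prediction table against a truth table of labeled
    (query_id, protein_id) pairs.

    Precision = TP/(TP+FP) and recall = TP/(TP+FN) come from the boolean
    calls when ``label_col`` names a column of binary calls (e.g. the
    meta-classifier output); otherwise a call is "predicted" iff the pair
    was reached at all.  The ROC sweeps every distinct score value; AUC is
    the trapezoidal area, NA when truth holds a single class.  The
    enrichment curve gives the fraction of positives recovered as a
    function of the fraction of the score-ranked list examined.
    """
    y_true, y_score = _align_scores(predictions, truth, score_col,
                                    higher_is_better)

    if label_col is not None:
        called = {
            (str(r["query_id"]), str(r["protein_id"]))
            for _, r in predictions.iterrows()
            if bool(r[label_col])
        }
    else:
        called = {
            (str(r["query_id"]), str(r["protein_id"]))
            for _, r in predictions.iterrows()
        }
    tp = fp = fn = tn = 0
    for _, r in truth.iterrows():
        key = (str(r["query_id"]), str(r["protein_id"]))
        hit = key in called
        if r["label"]:
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")

    if len(np.unique(y_true)) < 2:
        fpr, tpr, auc_val = np.array([]), np.array([]), None
    else:
        fpr, tpr, _ = roc_curve(y_true, y_score)
        auc_val = float(_auc(fpr, tpr))

    order = np.argsort(-y_score, kind="stable")
    ranked = y_true[order]
    n_pos = int(ranked.sum())
    frac_examined = np.arange(1, len(ranked) + 1) / len(ranked)
    frac_recovered = (np.cumsum(ranked) / n_pos if n_pos
                      else np.zeros(len(ranked)))
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "precision": precision,
        "recall": recall,
        "roc_points": list(zip(fpr.tolist(), tpr.tolist())),
        "auc": auc_val,
        "enrichment_curve": list(zip(frac_examined.tolist(),
                                     frac_recovered.tolist())),
    }


def ranking_auc(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    score_col: str = "score",
    higher_is_better: bool = True,
) -> float | None:
    """AUC of ranking truth pairs by a single prediction score."""
    y_true, y_score = _align_scores(predictions, truth, score_col,
                                    higher_is_better)
    if len(np.unique(y_true)) < 2:
        return None
    fpr, tpr, _ = roc_curve(y_true, y_score)
    return float(_auc(fpr, tpr))
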