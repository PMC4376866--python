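"""Distance-bounded shortest-path search and prediction scoring.

From each integrated query compound a Dijkstra search, cut off at a
maximum path distance, finds every reachable modeled target site.  A hit
is scored as the inverse of the summed edge distances of its path, then
standardized two ways: against the whole run's score population (Global
Z-score) and against the score distribution of its own target (Local
Z-score, which flags promiscuous pockets).
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import BipartiteNetwork, Prediction

log = logging.getLogger(__name__)

#: default maximum reachable path distance (roughly 4-5 moderate-similarity hops)
DEFAULT_DMAX = 10.0


def bounded_dijkstra(
    graph,
    source: str,
    d_max: float = DEFAULT_DMAX,
    weight: str = "distance",
) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Shortest paths from ``source`` to every node within distance ``d_max``.

    Returns ``{node: (distance, path)}`` including the source at distance
    0.  Ties are broken deterministically: among equal-distance paths the
    one with fewer hops wins, then the lexicographically smallest node
    sequence.  The frontier is pruned at ``d_max``, which is what makes
    the search cheap on large networks.
    """
    if source not in graph:
        raise KeyError(f"unknown source node {source!r}")
    if d_max <= 0:
        raise ValueError(f"d_max must be positive, got {d_max}")

    settled: dict[str, tuple[float, tuple[str, ...]]] = {}
    # heap entries ordered by (distance, hops, path) -> deterministic ties
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, (source,))]
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled[node] = (dist, path)
        for nbr, edata in sorted(graph[node].items()):
            if nbr in settled:
                continue
            w = float(edata[weight])
            if w <= 0:
                raise ValueError(f"non-positive edge distance on {node!r}-{nbr!r}")
            nd = dist + w
            if nd <= d_max:
                heapq.heappush(heap, (nd, hops + 1, path + (nbr,)))
    return settled


def score_path(distance: float) -> float:
    """Raw prediction score: the inverse of the summed edge distances.

    With every similarity <= 1 each hop costs at least 1, so the score
    lies in (0, 1] and decreases with path length.
    """
    if distance <= 0:
        raise ValueError(f"path distance must be positive, got {distance}")
    return 1.0 / distance


@dataclass
class ScoreStats:
    """Population statistics backing the Global and Local Z-scores."""

    mu_global: float
    sigma_global: float
    local: dict[str, tuple[float, float]]  # target id -> (mu, sigma)


def _normalize_scores(scores: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return scores.astype(float)
    if method == "minmax":
        lo, hi = scores.min(), scores.max()
        if hi == lo:
            return np.zeros_like(scores, dtype=float)
        return (scores - lo) / (hi - lo)
    raise ValueError(f"unknown normalization {method!r}")


def zscore_predictions(
    df: pd.DataFrame,
    normalize: str = "minmax",
    local_scope: str = "site",
) -> tuple[pd.DataFrame, ScoreStats]:
    """Attach Global and Local Z-scores to a prediction table.

    ``Gz = (s - mu_G) / sigma_G`` over the full run population and
    ``Lz = (s - mu_L) / sigma_L`` within the group of predictions sharing
    one target (``local_scope='site'`` groups by binding site,
    ``'protein'`` pools a protein's sites).  The raw score is first
    normalized per run (``none`` or ``minmax``); Z-scores are invariant to
    this affine rescaling, so the choice only affects the reported
    normalized column.  Degenerate groups (sigma = 0) get Z = 0 with a
    warning.
    """
    if df.empty:
        raise ValueError("cannot Z-score an empty prediction set")
    out = df.copy()
    s = _normalize_scores(out["score"].to_numpy(float), normalize)
    out["score_norm"] = s

    mu_g = float(s.mean())
    sigma_g = float(s.std(ddof=0))
    if sigma_g > 0:
        out["global_z"] = (s - mu_g) / sigma_g
    else:
        warnings.warn("score population has zero variance; global Z set to 0")
        out["global_z"] = 0.0

    group_col = "site_id" if local_scope == "site" else "protein_id"
    local: dict[str, tuple[float, float]] = {}
    lz = np.zeros(len(out))
    degenerate = 0
    for target, idx in out.groupby(group_col).groups.items():
        vals = out.loc[idx, "score_norm"].to_numpy(float)
        mu, sigma = float(vals.mean()), float(vals.std(ddof=0))
        local[str(target)] = (mu, sigma)
        if sigma > 0:
            lz[out.index.get_indexer(idx)] = (vals - mu) / sigma
        else:
            degenerate += 1
    if degenerate:
        warnings.warn(f"{degenerate} target group(s) with zero score variance; "
                      f"local Z set to 0")
    out["local_z"] = lz
    return out, ScoreStats(mu_g, sigma_g, local)


def predict_all(
    network: BipartiteNetwork,
    d_max: float = DEFAULT_DMAX,
    normalize: str = "minmax",
    local_scope: str = "site",
    queries: list[str] | None = None,
) -> pd.DataFrame:
    """Run the bounded search from every query and score all reachable
    modeled target sites.

    Returns one row per (query, reachable site) with columns ``query_id,
    protein_id, site_id, score, protein_score, global_z, local_z, path``;
    ``protein_score`` is the maximum site score of that protein for the
    query (best-pocket convention).  Unreachable queries contribute no
    rows and are logged.
    """
    targets = set(network.target_site_nodes)
    if queries is None:
        queries = network.query_nodes
    rows = []
    for q in queries:
        reached = bounded_dijkstra(network.graph, q, d_max=d_max)
        hits = {t: v for t, v in reached.items() if t in targets}
        if not hits:
            log.info("query %s reaches no target site within d_max=%s", q, d_max)
            continue
        for t, (dist, path) in sorted(hits.items()):
            site = network.sites[t]
            rows.append(
                {
                    "query_id": q,
                    "protein_id": site.protein_id,
                    "site_id": t,
                    "score": score_path(dist),
                    "path": "|".join(path),
                }
            )
    df = pd.DataFrame(
        rows, columns=["query_id", "protein_id", "site_id", "score", "path"]
    )
    if df.empty:
        return df
    df["protein_score"] = df.groupby(["query_id", "protein_id"])["score"] \
        .transform("max")
    df, _ = zscore_predictions(df, normalize=normalize, local_scope=local_scope)
    df = df.sort_values(["query_id", "protein_id", "site_id"]) \
        .reset_index(drop=True)
    return df


def predictions_from_frame(df: pd.DataFrame) -> list[Prediction]:
    """Materialize table rows as Prediction records (path provenance kept)."""
    preds = []
    for _, r in df.iterrows():
        preds.append(
            Prediction(
                query_id=r["query_id"],
                site_id=r["site_id"],
                protein_id=r["protein_id"],
                raw_score=float(r["score"]),
                path=tuple(str(r["path"]).split("|")),
                score_norm=float(r["score_norm"]) if "score_norm" in df else None,
                global_z=float(r["global_z"]) if "global_z" in df else None,
                local_z=float(r["local_z"]) if "local_z" in df else None,
            )
        )
    return preds
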