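"""Raw pairwise similarities that become network edges.

Three concerns live here: drug-likeness filtering of the ligand universe,
the feature vector describing a pair of compounds (fed to the pair
classifier), and thresholding / normalization of binding-site similarity
Z-scores into weighted edges.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _chem
from .model_io import Compound, SimilarityEdge

log = logging.getLogger(__name__)

#: drug-likeness cut applied to the ligand universe (inclusive)
WQED_THRESHOLD = 0.35

#: site-pair and model-site Z-score cuts (strict: edge requires z > cut)
SITE_ZMIN = 2.0
MODEL_SITE_ZMIN = 1.0

#: sentinel written into a pair-feature slot when a descriptor is missing
MISSING_FEATURE = -1.0

DruglikenessHook = Callable[[Compound], float]


def qed_hook(compound: Compound) -> float:
    """Default drug-likeness scorer: RDKit's weighted QED on the SMILES."""
    if compound.smiles is None:
        raise ValueError(f"compound {compound.id} has no SMILES to score")
    return _chem.qed_score(compound.smiles)


def filter_druglike(
    compounds: Sequence[Compound],
    threshold: float = WQED_THRESHOLD,
    scorer: DruglikenessHook | None = None,
) -> list[Compound]:
    """Keep compounds with drug-likeness (wQED) >= ``threshold``.

    Compounds missing a wqed value are scored with ``scorer`` when one is
    configured; otherwise they are fatal.  Order is preserved and the
    number of removed compounds is logged.
    """
    missing = [c.id for c in compounds if c.wqed is None]
    if missing and scorer is None:
        raise ValueError(
            f"{len(missing)} compound(s) lack wqed and no scorer hook is "
            f"configured: {', '.join(missing[:10])}"
        )
    kept = []
    for c in compounds:
        wqed = c.wqed if c.wqed is not None else scorer(c)
        if c.wqed is None:
            c.wqed = float(wqed)
        if wqed >= threshold:
            kept.append(c)
    log.info("drug-likeness filter: kept %d / %d compounds (wQED >= %s)",
             len(kept), len(compounds), threshold)
    return kept


def featurize_compound(
    compound: Compound,
    n_bits: int = _chem.DEFAULT_FP_BITS,
    radius: int = _chem.DEFAULT_FP_RADIUS,
) -> Compound:
    """Fill fingerprint and descriptor block from the SMILES, in place."""
    if compound.smiles is None:
        raise ValueError(f"compound {compound.id} has no SMILES")
    compound.fingerprint = _chem.fingerprint_from_smiles(
        compound.smiles, n_bits=n_bits, radius=radius
    )
    compound.descriptors.update(_chem.descriptors_from_smiles(compound.smiles))
    return compound


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over fingerprint bits."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b)) / union


#: fixed order of the pair-feature vector
PAIR_FEATURE_NAMES = (
    "tanimoto",
    "abs_d_mw",
    "abs_d_logp",
    "abs_d_rotatable_bonds",
    "abs_d_aromatic_rings",
    "abs_d_hbd",
    "abs_d_hba",
    "ratio_mw",
    "ratio_tpsa",
)

_DELTA_FIELDS = ("mw", "logp", "rotatable_bonds", "aromatic_rings", "hbd", "hba")
_RATIO_FIELDS = ("mw", "tpsa")


def ligand_pair_features(a: Compound, b: Compound) -> np.ndarray:
    """Symmetric feature vector for a pair of compounds.

    Fingerprint Tanimoto, absolute descriptor deltas and min/max descriptor
    ratios, in the order of :data:`PAIR_FEATURE_NAMES`.  A missing
    descriptor yields the :data:`MISSING_FEATURE` sentinel for that slot
    and a warning.
    """
    if a.fingerprint is None or b.fingerprint is None:
        raise ValueError("both compounds must carry fingerprints")
    feats = [tanimoto(a.fingerprint, b.fingerprint)]
    flagged = []
    for name in _DELTA_FIELDS:
        if name in a.descriptors and name in b.descriptors:
            feats.append(abs(a.descriptors[name] - b.descriptors[name]))
        else:
            feats.append(MISSING_FEATURE)
            flagged.append(name)
    for name in _RATIO_FIELDS:
        if name in a.descriptors and name in b.descriptors:
            lo, hi = sorted((a.descriptors[name], b.descriptors[name]))
            feats.append(lo / hi if hi > 0 else 1.0)
        else:
            feats.append(MISSING_FEATURE)
            flagged.append(name)
    if flagged:
        warnings.warn(
            f"pair ({a.id}, {b.id}): missing descriptors {sorted(set(flagged))}; "
            f"sentinel used"
        )
    return np.asarray(feats, dtype=float)


def normalize_z(z: float, z_ref: float) -> float:
    """Map a positive similarity Z-score into (0, 1]: z / (z + z_ref).

    Strictly increasing in z; equals 0.5 at the threshold z = z_ref and
    approaches 1 for very large Z.  ``z_ref`` is the acceptance threshold
    of the context (2.0 for within-network site pairs, 1.0 for model-site
    integration).
    """
    if z <= 0:
        raise ValueError(f"normalize_z expects z > 0, got {z}")
    return float(z / (z + z_ref))


def site_similarity_to_edge(
    a: str,
    b: str,
    zscore: float,
    zmin: float = SITE_ZMIN,
    kind: str = "site",
) -> SimilarityEdge | None:
    """Turn a site-pair structural-comparison Z-score into an edge.

    Returns an edge only when ``zscore > zmin`` (strict); the edge weight
    is the normalized Z-score.
    """
    if not np.isfinite(zscore):
        raise ValueError(f"non-finite Z-score for pair ({a}, {b})")
    if zscore <= zmin:
        return None
    return SimilarityEdge(a, b, similarity=normalize_z(zscore, zmin), kind=kind)


def ligand_edges_from_table(
    pairs: Iterable[tuple[str, str, float]],
) -> list[SimilarityEdge]:
    """Bypass path: precomputed ligand-pair probabilities -> edges."""
    return [SimilarityEdge(a, b, similarity=v, kind="ligand")
            for a, b, v in pairs if a != b and v > 0]


def site_edges_from_table(
    pairs: Iterable[tuple[str, str, float]],
    zmin: float = SITE_ZMIN,
    kind: str = "site",
) -> list[SimilarityEdge]:
    """Bypass path: precomputed site-pair Z-scores -> thresholded edges."""
    edges = []
    for a, b, z in pairs:
        if a == b:
            continue
        e = site_similarity_to_edge(a, b, z, zmin=zmin, kind=kind)
        if e is not None:
            edges.append(e)
    return edges
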