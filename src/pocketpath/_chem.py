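"""Thin RDKit wrappers: SMILES parsing, fingerprints, descriptor blocks.

All chemistry in the package funnels through this module so the rest of
the code never touches RDKit directly and pre-featurized (SMILES-free)
compounds remain first-class citizens.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, QED, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

DEFAULT_FP_BITS = 2048
DEFAULT_FP_RADIUS = 2

#: descriptor names every featurized compound carries
DESCRIPTOR_NAMES = (
    "mw",
    "logp",
    "tpsa",
    "hbd",
    "hba",
    "rotatable_bonds",
    "aromatic_rings",
)


def mol_from_smiles(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical form used for structure-identity checks."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def fingerprint_from_smiles(
    smiles: str, n_bits: int = DEFAULT_FP_BITS, radius: int = DEFAULT_FP_RADIUS
) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint as a uint8 0/1 vector."""
    mol = mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def descriptors_from_smiles(smiles: str) -> dict[str, float]:
    mol = mol_from_smiles(smiles)
    return {
        "mw": Descriptors.MolWt(mol),
        "logp": Descriptors.MolLogP(mol),
        "tpsa": Descriptors.TPSA(mol),
        "hbd": float(Descriptors.NumHDonors(mol)),
        "hba": float(Descriptors.NumHAcceptors(mol)),
        "rotatable_bonds": float(Descriptors.NumRotatableBonds(mol)),
        "aromatic_rings": float(Descriptors.NumAromaticRings(mol)),
    }


def qed_score(smiles: str) -> float:
    """Weighted quantitative estimate of drug-likeness in [0, 1].

    Offered as the default pluggable scorer for compounds that arrive
    without a drug-likeness column.
    """
    return float(QED.weights_max(mol_from_smiles(smiles)))
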