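"""Compound featurization via extended-connectivity fingerprints (ECFP).

Circular (Morgan) substructure identifiers up to a radius are hashed and
folded modulo ``nbits`` into a binary vector; the default 1024-bit,
radius-2 fingerprint is the classic ECFP4.  Fingerprint computation
delegates to RDKit's Morgan generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")

__all__ = ["CompoundFingerprint", "ecfp", "jaccard"]


@dataclass(frozen=True)
class CompoundFingerprint:
    """Binary fingerprint vector plus its population count."""

    bits: np.ndarray  # uint8 vector of length nbits

    def __post_init__(self):
        if self.bits.ndim != 1 or len(self.bits) < 1:
            raise ValueError("bits must be a non-empty 1-D vector")

    @property
    def nbits(self) -> int:
        return len(self.bits)

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())

    @property
    def on_bits(self) -> set[int]:
        return set(np.flatnonzero(self.bits))


def ecfp(smiles: str, radius: int = 2, nbits: int = 1024
         ) -> CompoundFingerprint:
    """Morgan/circular fingerprint of a SMILES string.

    Deterministic and invariant to the SMILES atom ordering of the same
    molecule.  Raises ValueError for unparseable SMILES.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if nbits < 1:
        raise ValueError("nbits must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=nbits
    )
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return CompoundFingerprint(bits=bits)


def jaccard(a: CompoundFingerprint, b: CompoundFingerprint) -> float:
    """Jaccard (Tanimoto) coefficient |a AND b| / |a OR b| of two
    fingerprints.  Two all-zero fingerprints are defined as identical
    (coefficient 1.0)."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint lengths differ: {a.nbits} vs {b.nbits}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        logger.debug("jaccard of two empty fingerprints defined as 1.0")
        return 1.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union
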