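"""Chemistry and string primitives.

SMILES validity and canonicalization, ECFP4-style circular fingerprints,
Tanimoto similarity on bit sets, and Levenshtein distance / normalized
string similarity.  These are the building blocks of the rediscovery
oracles and of the sphere-exclusion diversity metric.

Canonicalization uses RDKit's canonical SMILES algorithm; a single
algorithm is used consistently for a whole run, which is all the
deduplication logic requires (byte-identity across toolkits is not
promised).  Invalidity is a value (``None``), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")  # parse failures are expected, not noteworthy

FP_RADIUS = 2
FP_BITS = 2048

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint (radius-2, 2048 bits)."""

    bits: np.ndarray  # bool array of length FP_BITS

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))
        if self.bits.shape != (FP_BITS,):
            raise ValueError(f"fingerprint must have {FP_BITS} bits")

    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())


def validate_and_canonicalize(smiles: str) -> str | None:
    """Return the canonical SMILES if the string parses, else ``None``.

    Idempotent: canonicalizing a canonical string returns it unchanged.
    """
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def is_valid(smiles: str) -> bool:
    return validate_and_canonicalize(smiles) is not None


def ecfp4(canonical: str) -> Fingerprint:
    """Radius-2 hashed circular fingerprint of a valid (canonical) SMILES."""
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        raise ValueError(f"not a valid SMILES: {canonical!r}")
    return Fingerprint(_morgan.GetFingerprintAsNumPy(mol).astype(bool))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a ∩ b| / |a ∪ b| on bit sets; 0 when both sets are empty."""
    inter = np.count_nonzero(a.bits & b.bits)
    union = np.count_nonzero(a.bits | b.bits)
    if union == 0:
        return 0.0
    return inter / union


def levenshtein_distance(a: str, b: str) -> int:
    """Minimal number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b``."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def levenshtein_similarity(a: str, b: str) -> float:
    """Normalized edit similarity 1 - LD(a, b) / max(|a|, |b|).

    Symmetric, in [0, 1], and 1 exactly when the strings are equal
    (including the both-empty case).
    """
    if a == b:
        return 1.0
    denom = max(len(a), len(b))
    return 1.0 - levenshtein_distance(a, b) / denom
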