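"""2D structural similarity search for hit expansion.

Confirmed scaffolds are expanded into candidate derivative sets by circular
(Morgan) fingerprint similarity over a compound library — a 2D search that
needs no ligand pose.  Structures are canonicalised, salts stripped
(largest organic fragment kept) and stereochemistry ignored, so the search
operates at scaffold level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .io import Compound

__all__ = ["Fingerprint", "fingerprint", "tanimoto", "search"]

logger = logging.getLogger(__name__)


class SmilesParseError(ValueError):
    """Unparseable SMILES, naming the offending record."""


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint of a canonicalised 2D structure."""

    bits: bytes  # packed bit vector
    n_bits: int
    n_set: int

    def as_array(self) -> np.ndarray:
        return np.unpackbits(
            np.frombuffer(self.bits, dtype=np.uint8), count=self.n_bits
        ).astype(bool)


def _prepare_mol(smiles: str, record: str | None = None) -> Chem.Mol:
    label = record or smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"unparseable SMILES in record {label!r}")
    # keep the largest fragment (salt stripping), drop stereochemistry
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    Chem.RemoveStereochemistry(mol)
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical, salt-stripped, stereo-free SMILES."""
    return Chem.MolToSmiles(_prepare_mol(smiles))


def fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan (circular-environment) fingerprint of a SMILES string.

    The structure is canonicalised first, so the result is invariant to
    input atom ordering and aromatic/Kekulé notation.
    """
    mol = _prepare_mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.array(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    return Fingerprint(
        bits=np.packbits(arr).tobytes(),
        n_bits=n_bits,
        n_set=int(arr.sum()),
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∧b|/|a∨b| in [0, 1]; 1.0 when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    av = np.frombuffer(a.bits, dtype=np.uint8)
    bv = np.frombuffer(b.bits, dtype=np.uint8)
    inter = int(np.bitwise_count(av & bv).sum())
    union = int(np.bitwise_count(av | bv).sum())
    if union == 0:
        return 1.0
    return inter / union


def search(
    query_smiles: str,
    library: list[Compound],
    threshold: float = 0.6,
    top_n: int = 10,
    radius: int = 2,
    n_bits: int = 2048,
) -> list[tuple[Compound, float]]:
    """Rank library members by similarity to a query scaffold.

    Returns members with Tanimoto similarity >= ``threshold``, most similar
    first (ties broken by compound id), truncated to ``top_n``.  Library
    records identical to the query structure are excluded;
    unparseable records are skipped with a warning.
    """
    if not library:
        raise ValueError("library must be non-empty")
    query_fp = fingerprint(query_smiles, radius=radius, n_bits=n_bits)
    query_canonical = canonical_smiles(query_smiles)

    scored = []
    n_parsed = 0
    for compound in library:
        try:
            canon = canonical_smiles(compound.smiles)
            fp = fingerprint(compound.smiles, radius=radius, n_bits=n_bits)
        except SmilesParseError:
            logger.warning("skipping unparseable library record %s", compound.compound_id)
            continue
        n_parsed += 1
        if canon == query_canonical:
            continue  # the query itself
        sim = tanimoto(query_fp, fp)
        if sim >= threshold:
            scored.append((compound, sim))
    if n_parsed == 0:
        logger.warning("no parseable library records; empty result")
        return []
    scored.sort(key=lambda t: (-t[1], t[0].compound_id))
    return scored[:top_n]
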