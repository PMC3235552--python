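"""Circular (ECFP-style) fingerprints, Tanimoto similarity and diversity.

Fingerprints are Morgan environments of radius 2 (the ECFP-4 equivalent)
hashed and folded into a fixed power-of-two bit space (default 2048).  The
library-diversity statistic is the fraction of all unordered fragment pairs
whose Tanimoto coefficient exceeds a threshold (default 0.26); a diverse
fragment library keeps this fraction in the low percent range.

Similarity to the endogenous ligands histamine and serotonin, profiled per
hit class at the same threshold, distinguishes histamine-like selective hits
from the chemically novel dual binders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit.Chem import rdFingerprintGenerator

from . import labels
from .chem import Molecule, parse_structure

__all__ = [
    "Fingerprint",
    "HISTAMINE_SMILES",
    "SEROTONIN_SMILES",
    "reference_ligands",
    "circular_fingerprint",
    "tanimoto",
    "pairwise_diversity",
    "endogenous_similarity_profile",
]

# Standard structures of the two endogenous ligands (formulas C5H9N3 and
# C10H12N2O); shipped as package constants for the similarity profiling.
HISTAMINE_SMILES = "NCCc1c[nH]cn1"
SEROTONIN_SMILES = "NCCc1c[nH]c2ccc(O)cc12"


def reference_ligands() -> dict[str, Molecule]:
    return {
        "histamine": parse_structure(HISTAMINE_SMILES, "histamine"),
        "serotonin": parse_structure(SEROTONIN_SMILES, "serotonin"),
    }


@dataclass(frozen=True)
class Fingerprint:
    """Folded binary circular fingerprint: the set of on-bit positions."""

    bits: frozenset[int]
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if self.n_bits <= 0 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError(f"n_bits must be a power of two, got {self.n_bits}")
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit position outside [0, n_bits)")


_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _GENERATORS[key]


def circular_fingerprint(m: Molecule, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan fingerprint of the molecule; invariant to input atom order.

    Iterative neighborhood hashing over the standard atom invariants
    (atomic number, degree, H count, charge, ring membership) for
    iterations 0..radius, deduplicated and folded into ``n_bits``.
    """
    if n_bits <= 0 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two, got {n_bits}")
    bv = _generator(radius, n_bits).GetFingerprint(m.rdmol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A ∩ B| / |A ∪ B| over on-bit sets; 1.0 when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint size mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def pairwise_diversity(
    library: Sequence[Fingerprint], threshold: float = 0.26
) -> tuple[float, int]:
    """Fraction of unordered fingerprint pairs with Tc strictly above threshold.

    Returns ``(fraction, n_pairs)`` over all n(n-1)/2 pairs.  A low fraction
    (a few percent) indicates a structurally diverse library.
    """
    n = len(library)
    if n < 2:
        raise ValueError("pairwise diversity needs at least two fingerprints")
    n_pairs = n * (n - 1) // 2
    above = 0
    bitsets = [fp.bits for fp in library]
    for i in range(n):
        if library[i].n_bits != library[0].n_bits:
            raise ValueError("fingerprint size mismatch within library")
        bi = bitsets[i]
        for j in range(i + 1, n):
            bj = bitsets[j]
            union = len(bi | bj)
            tc = (len(bi & bj) / union) if union else 1.0
            if tc > threshold:
                above += 1
    return above / n_pairs, n_pairs


def endogenous_similarity_profile(
    fingerprints: Mapping[str, Fingerprint],
    class_labels: Mapping[str, str],
    references: Mapping[str, Molecule] | None = None,
    threshold: float = 0.26,
    radius: int = 2,
    n_bits: int = 2048,
) -> pd.DataFrame:
    """Per-class, per-reference fraction of fragments similar to a reference.

    ``fingerprints`` maps fragment id to its fingerprint, ``class_labels``
    maps fragment id to a hit class.  Similarity means Tc strictly above
    ``threshold``.  Classes with no members are absent from the output.
    """
    references = references if references is not None else reference_ligands()
    unknown = sorted(set(class_labels.values()) - set(labels.ALL_LABELS))
    if unknown:
        raise ValueError(f"unknown hit-class labels: {unknown}")
    ref_fps = {
        name: circular_fingerprint(mol, radius=radius, n_bits=n_bits)
        for name, mol in references.items()
    }
    by_class: dict[str, list[str]] = {}
    for frag_id, hit_class in class_labels.items():
        by_class.setdefault(hit_class, []).append(frag_id)
    rows = []
    for hit_class in labels.ALL_LABELS:
        members = by_class.get(hit_class)
        if not members:
            continue
        for ref_name, ref_fp in ref_fps.items():
            count = sum(
                1 for frag_id in members if tanimoto(fingerprints[frag_id], ref_fp) > threshold
            )
            rows.append(
                {
                    "hit_class": hit_class,
                    "reference": ref_name,
                    "n": len(members),
                    "n_similar": count,
                    "frac_similar": count / len(members),
                }
            )
    return pd.DataFrame(rows, columns=["hit_class", "reference", "n", "n_similar", "frac_similar"])
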