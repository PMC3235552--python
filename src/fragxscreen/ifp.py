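"""Molecular interaction fingerprints (IFP) from residue-level annotations.

An IFP encodes a ligand–receptor complex as an ordered bit string over a
fixed residue panel: 7 bits per residue, one per interaction type, in the
standard fixed order

    hydrophobic, aromatic face-to-face, aromatic edge-to-face,
    H-bond donated by the protein, H-bond accepted by the protein,
    ionic with a protein cation, ionic with a protein anion.

Bit ``i*7 + t`` is residue ``panel[i]``, type ``INTERACTION_TYPES[t]``; the
layout is stable and the annotation → bit string mapping round-trips
losslessly.  This module consumes interaction *annotations* (text tables,
e.g. from docking poses or crystal structures inspected elsewhere); it does
not detect interactions from 3D coordinates.

Comparing the IFPs of one ligand in two different receptors — a GPCR and an
ion channel, say — requires an explicit residue pairing map that aligns the
two panels position-by-position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "INTERACTION_TYPES",
    "InteractionFingerprint",
    "build_ifp",
    "ifp_tanimoto",
]

INTERACTION_TYPES = (
    "hydrophobic",
    "aromatic_face_to_face",
    "aromatic_edge_to_face",
    "hbond_protein_donor",
    "hbond_protein_acceptor",
    "ionic_protein_cation",
    "ionic_protein_anion",
)

_TYPE_INDEX = {name: i for i, name in enumerate(INTERACTION_TYPES)}
N_TYPES = len(INTERACTION_TYPES)


@dataclass(frozen=True)
class InteractionFingerprint:
    """Bit string over (residue, interaction type) pairs for one complex."""

    panel: tuple[str, ...]
    bits: frozenset[int]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("residue panel labels must be unique")
        n = len(self.panel) * N_TYPES
        if any(b < 0 or b >= n for b in self.bits):
            raise ValueError("bit position outside the panel bit string")

    @property
    def length(self) -> int:
        return len(self.panel) * N_TYPES

    def bit_index(self, residue: str, interaction_type: str) -> int:
        """Documented offset: residue position × 7 + type position."""
        try:
            r = self.panel.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue!r} not in panel") from None
        if interaction_type not in _TYPE_INDEX:
            raise KeyError(f"unknown interaction type {interaction_type!r}")
        return r * N_TYPES + _TYPE_INDEX[interaction_type]

    def to_bitstring(self) -> str:
        return "".join("1" if i in self.bits else "0" for i in range(self.length))

    def annotations(self) -> list[tuple[str, str]]:
        """Recover the (residue, type) annotations; inverse of build_ifp."""
        return [
            (self.panel[b // N_TYPES], INTERACTION_TYPES[b % N_TYPES])
            for b in sorted(self.bits)
        ]


def build_ifp(
    annotations: Iterable[tuple[str, str]],
    panel: Sequence[str],
    label: str = "",
) -> InteractionFingerprint:
    """Build an IFP from (residue, interaction type) annotations.

    Every annotated residue must be on the panel and every type must come
    from the 7-type vocabulary; unannotated residues contribute zero bits.
    """
    panel = tuple(panel)
    residue_index = {res: i for i, res in enumerate(panel)}
    if len(residue_index) != len(panel):
        raise ValueError("residue panel labels must be unique")
    bits: set[int] = set()
    for residue, interaction_type in annotations:
        if residue not in residue_index:
            raise KeyError(f"annotated residue {residue!r} not in panel {list(panel)}")
        if interaction_type not in _TYPE_INDEX:
            raise KeyError(
                f"unknown interaction type {interaction_type!r}; "
                f"expected one of {list(INTERACTION_TYPES)}"
            )
        bits.add(residue_index[residue] * N_TYPES + _TYPE_INDEX[interaction_type])
    return InteractionFingerprint(panel=panel, bits=frozenset(bits), label=label)


def ifp_tanimoto(
    a: InteractionFingerprint,
    b: InteractionFingerprint,
    pairing: Mapping[str, str] | None = None,
) -> float:
    """Tanimoto over set bits; two all-zero fingerprints compare as 1.0.

    With identical panels the comparison is positional.  Across receptors,
    ``pairing`` maps residues of ``a`` to equivalent residues of ``b`` (e.g.
    aligning transmembrane positions with binding-loop residues); unpaired
    residues of either panel still contribute their set bits to the union.
    """
    if pairing is None:
        if a.panel != b.panel:
            raise ValueError(
                "panels differ; supply a residue pairing map for cross-receptor comparison"
            )
        mapped_a = a.bits
        b_bits = b.bits
    else:
        bad_src = sorted(set(pairing) - set(a.panel))
        bad_dst = sorted(set(pairing.values()) - set(b.panel))
        if bad_src or bad_dst:
            raise ValueError(f"pairing references unknown residues: {bad_src + bad_dst}")
        mapped_a = set()
        for bit in a.bits:
            residue = a.panel[bit // N_TYPES]
            t = bit % N_TYPES
            if residue in pairing:
                mapped_a.add(b.panel.index(pairing[residue]) * N_TYPES + t)
            else:
                # unpaired residue: a private bit outside b's space
                mapped_a.add(b.length + bit)
        b_bits = b.bits
    union = len(set(mapped_a) | b_bits)
    if union == 0:
        return 1.0
    return len(set(mapped_a) & b_bits) / union
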