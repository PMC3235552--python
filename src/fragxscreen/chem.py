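"""Chemical-graph data model and atomic-level physicochemical descriptors.

The :class:`Molecule` wraps a sanitized RDKit molecule (Hückel aromaticity,
implicit hydrogens) so that every downstream stage — fragment-rule filtering,
scaffold classification, fingerprinting, screen analysis — sees one consistent
chemistry model.  Descriptor conventions used throughout:

* H-bond donors are counted as donor *atoms* (N or O carrying at least one
  hydrogen), not as donor hydrogens.  Histamine therefore scores 2 (primary
  amine plus imidazole NH).
* H-bond acceptors follow the Lipinski N+O atom count.
* Rotatable bonds are acyclic single bonds between two non-terminal heavy
  atoms, excluding amide C–N (the strict Veber/Daylight definition).
* clogP is the Wildman–Crippen atomic-contribution estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "DescriptorRecord",
    "StructureError",
    "parse_structure",
    "largest_component",
    "heavy_atom_count",
    "hbond_donors",
    "hbond_acceptors",
    "rotatable_bonds",
    "estimate_clogp",
    "sssr_rings",
    "ring_atom_count",
    "bond_count",
    "sum_atomic_numbers",
    "compute_descriptors",
    "descriptor_table",
    "read_smiles_file",
    "read_sdf",
    "write_smiles_file",
    "write_descriptor_csv",
    "DESCRIPTOR_COLUMNS",
]


class StructureError(ValueError):
    """Raised when a structure cannot be parsed or violates the model."""


@dataclass(frozen=True)
class Molecule:
    """Connected heavy-atom chemical graph with perceived aromaticity.

    ``atoms`` holds ``(atomic number, formal charge, aromatic flag, implicit
    hydrogen count)`` per heavy atom; ``bonds`` holds ``(i, j, order)`` with
    ``i < j`` and order one of ``1, 2, 3, "ar"``.  ``smiles`` is the RDKit
    canonical SMILES, so two :class:`Molecule` objects describing the same
    structure compare equal on it regardless of input atom order.
    """

    identifier: str
    smiles: str
    atoms: tuple[tuple[int, int, bool, int], ...]
    bonds: tuple[tuple[int, int, object], ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureError(f"{self.identifier}: invalid bond ({i},{j})")
            if (i, j) in seen:
                raise StructureError(f"{self.identifier}: duplicate bond ({i},{j})")
            seen.add((i, j))

    @property
    def rdmol(self) -> Chem.Mol:
        """Sanitized RDKit molecule (reconstructed from canonical SMILES)."""
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always reparses
            raise StructureError(f"{self.identifier}: stored SMILES invalid")
        return mol


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


def _from_rdmol(mol: Chem.Mol, identifier: str) -> Molecule:
    if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
        mol = Chem.RemoveHs(mol)
    atoms = tuple(
        (a.GetAtomicNum(), a.GetFormalCharge(), a.GetIsAromatic(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        order = _BOND_ORDER.get(b.GetBondType())
        if order is None:
            raise StructureError(f"{identifier}: unsupported bond type {b.GetBondType()}")
        bonds.append((i, j, order))
    return Molecule(
        identifier=identifier,
        smiles=Chem.MolToSmiles(mol),
        atoms=atoms,
        bonds=tuple(sorted(bonds, key=lambda t: (t[0], t[1]))),
    )


def parse_structure(text: str, identifier: str = "") -> Molecule:
    """Parse a SMILES string into a sanitized, connected :class:`Molecule`.

    Raises :class:`StructureError` for syntactically invalid SMILES and for
    multi-component inputs (salts must be stripped first; see
    :func:`largest_component`).
    """
    if not text or not text.strip():
        raise StructureError(f"{identifier or '<input>'}: empty SMILES")
    text = text.strip()
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureError(
            f"{identifier or '<input>'}: cannot parse SMILES {text!r}"
            f" (syntax or valence error within the {len(text)}-character token stream)"
        )
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise StructureError(
            f"{identifier or '<input>'}: multi-component SMILES {text!r} "
            f"({len(frags)} fragments); strip salts with largest_component() first"
        )
    return _from_rdmol(mol, identifier or Chem.MolToSmiles(mol))


def largest_component(text: str) -> str:
    """Return the SMILES of the largest component (salt stripping helper).

    Must be invoked explicitly; :func:`parse_structure` rejects mixtures.
    Equal-size ties are broken deterministically on canonical SMILES.
    """
    mol = Chem.MolFromSmiles(text.strip()) if text and text.strip() else None
    if mol is None:
        raise StructureError(f"cannot parse SMILES {text!r}")
    parts = Chem.GetMolFrags(mol, asMols=True)
    best = max(parts, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return Chem.MolToSmiles(best)


# ---------------------------------------------------------------------------
# atomic-level descriptors
# ---------------------------------------------------------------------------

def heavy_atom_count(m: Molecule) -> int:
    """Number of non-hydrogen atoms (HA)."""
    return len(m.atoms)


def hbond_donors(m: Molecule) -> int:
    """Donor atoms: N or O bearing at least one hydrogen."""
    return sum(1 for z, _q, _ar, h in m.atoms if z in (7, 8) and h > 0)


def hbond_acceptors(m: Molecule) -> int:
    """Acceptor atoms under the Lipinski N+O convention."""
    return sum(1 for z, _q, _ar, _h in m.atoms if z in (7, 8))


def rotatable_bonds(m: Molecule) -> int:
    """Acyclic single non-amide bonds between non-terminal heavy atoms."""
    return rdMolDescriptors.CalcNumRotatableBonds(
        m.rdmol, rdMolDescriptors.NumRotatableBondsOptions.Strict
    )


def estimate_clogp(m: Molecule) -> float:
    """Wildman–Crippen atomic-contribution logP estimate."""
    return Crippen.MolLogP(m.rdmol)


def sssr_rings(m: Molecule) -> list[frozenset[int]]:
    """Smallest set of smallest rings as atom-index sets.

    For a connected graph the number of rings equals the circuit rank
    ``bonds - atoms + 1``; an acyclic molecule yields ``[]``.
    """
    mol = m.rdmol
    return [frozenset(ring) for ring in Chem.GetSSSR(mol)]


def ring_atom_count(m: Molecule) -> int:
    """Number of heavy atoms belonging to at least one ring."""
    mol = m.rdmol
    return sum(1 for a in mol.GetAtoms() if a.IsInRing())


def bond_count(m: Molecule) -> int:
    """Number of heavy-heavy bonds."""
    return len(m.bonds)


def sum_atomic_numbers(m: Molecule) -> int:
    """Sum of atomic numbers over heavy atoms."""
    return sum(z for z, _q, _ar, _h in m.atoms)


@dataclass(frozen=True)
class DescriptorRecord:
    """Per-fragment physicochemical descriptor vector.

    ``sssr_ring_count`` equals the circuit rank of the (connected) graph;
    ``ring_atoms`` can never exceed ``heavy_atoms``.
    """

    identifier: str
    heavy_atoms: int
    hbd: int
    hba: int
    rotatable_bonds: int
    clogp: float
    ring_atoms: int
    sssr_ring_count: int
    bond_count: int
    sum_atomic_numbers: int

    def __post_init__(self) -> None:
        counts = (
            self.heavy_atoms,
            self.hbd,
            self.hba,
            self.rotatable_bonds,
            self.ring_atoms,
            self.sssr_ring_count,
            self.bond_count,
            self.sum_atomic_numbers,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.identifier}: negative descriptor count")
        if self.ring_atoms > self.heavy_atoms:
            raise ValueError(f"{self.identifier}: ring atoms exceed heavy atoms")


DESCRIPTOR_COLUMNS = [
    "identifier",
    "heavy_atoms",
    "hbd",
    "hba",
    "rotatable_bonds",
    "clogp",
    "ring_atoms",
    "sssr_ring_count",
    "bond_count",
    "sum_atomic_numbers",
]


def compute_descriptors(m: Molecule) -> DescriptorRecord:
    """Evaluate the full descriptor vector for one molecule."""
    return DescriptorRecord(
        identifier=m.identifier,
        heavy_atoms=heavy_atom_count(m),
        hbd=hbond_donors(m),
        hba=hbond_acceptors(m),
        rotatable_bonds=rotatable_bonds(m),
        clogp=estimate_clogp(m),
        ring_atoms=ring_atom_count(m),
        sssr_ring_count=len(sssr_rings(m)),
        bond_count=bond_count(m),
        sum_atomic_numbers=sum_atomic_numbers(m),
    )


def descriptor_table(molecules: Iterable[Molecule]) -> pd.DataFrame:
    """Descriptor vectors for a library, one row per molecule."""
    records = [compute_descriptors(m) for m in molecules]
    return pd.DataFrame(
        [[getattr(r, c) for c in DESCRIPTOR_COLUMNS] for r in records],
        columns=DESCRIPTOR_COLUMNS,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[Molecule]:
    """Read a .smi file: one SMILES plus optional whitespace-delimited id per line."""
    molecules: list[Molecule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            identifier = parts[1] if len(parts) > 1 else f"mol{lineno}"
            molecules.append(parse_structure(smiles, identifier))
    return molecules


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read a V2000 SDF; molecule names come from the title line or _Name."""
    molecules: list[Molecule] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"{path}: record {idx + 1} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{idx + 1}"
        if len(Chem.GetMolFrags(mol)) > 1:
            raise StructureError(f"{path}: record {name} is multi-component")
        molecules.append(_from_rdmol(mol, name))
    return molecules


def write_smiles_file(molecules: Sequence[Molecule], path: str | Path) -> None:
    """Write canonical SMILES, one ``smiles<TAB>id`` pair per line."""
    with open(path, "w") as fh:
        for m in molecules:
            fh.write(f"{m.smiles}\t{m.identifier}\n")


def write_descriptor_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a descriptor table with the fixed, documented column order."""
    table.loc[:, DESCRIPTOR_COLUMNS].to_csv(path, index=False, float_format="%.4f")
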