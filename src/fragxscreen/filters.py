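"""Fragment-library admission rules.

A fragment is admitted when it satisfies all of: heavy atoms <= 22,
clogP < 3, H-bond donors <= 3, H-bond acceptors <= 3, rotatable bonds <= 5,
at least one ring, and no reactive functional group.  Boundary semantics are
inclusive for the counts and strictly-less-than for clogP.

The reactive-group exclusion set ships as a plain-text SMARTS table
(``data/reactive_groups.tsv``) so users can extend it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import DescriptorRecord, Molecule, compute_descriptors

__all__ = [
    "FragmentRules",
    "FilterVerdict",
    "DEFAULT_RULES",
    "load_reactive_patterns",
    "match_reactive_groups",
    "evaluate_fragment_rules",
    "filter_library",
]

RULE_CODES = ("HA", "CLOGP", "HBD", "HBA", "ROTB", "NO_RING", "REACTIVE")


@dataclass(frozen=True)
class FragmentRules:
    """Thresholds of the admission rules; defaults are the published bounds."""

    max_heavy_atoms: int = 22
    max_clogp: float = 3.0  # strict: clogP must be < this
    max_hbd: int = 3
    max_hba: int = 3
    max_rotatable: int = 5
    require_ring: bool = True
    exclude_reactive: bool = True


DEFAULT_RULES = FragmentRules()


@dataclass(frozen=True)
class FilterVerdict:
    identifier: str
    passed: bool
    failed_rules: tuple[str, ...]
    matched_reactive: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_rules) == 0):
            raise ValueError(f"{self.identifier}: passed flag inconsistent with failed rules")


def _pattern_file() -> Path:
    return Path(str(resources.files("fragxscreen").joinpath("data/reactive_groups.tsv")))


def load_reactive_patterns(path: str | Path | None = None) -> list[tuple[str, Chem.Mol]]:
    """Load the named SMARTS exclusion patterns, preserving file order."""
    path = Path(path) if path is not None else _pattern_file()
    patterns: list[tuple[str, Chem.Mol]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"invalid SMARTS for pattern {name!r}: {smarts}")
        patterns.append((name, query))
    return patterns


_PATTERN_CACHE: list[tuple[str, Chem.Mol]] | None = None


def match_reactive_groups(m: Molecule, patterns: list[tuple[str, Chem.Mol]] | None = None) -> list[str]:
    """Names of exclusion patterns the molecule matches, in file order."""
    global _PATTERN_CACHE
    if patterns is None:
        if _PATTERN_CACHE is None:
            _PATTERN_CACHE = load_reactive_patterns()
        patterns = _PATTERN_CACHE
    mol = m.rdmol
    return [name for name, query in patterns if mol.HasSubstructMatch(query)]


def evaluate_fragment_rules(
    d: DescriptorRecord,
    m: Molecule,
    rules: FragmentRules = DEFAULT_RULES,
) -> FilterVerdict:
    """Apply the admission rules to one fragment; every violation is listed."""
    failed: list[str] = []
    if d.heavy_atoms > rules.max_heavy_atoms:
        failed.append("HA")
    if not d.clogp < rules.max_clogp:
        failed.append("CLOGP")
    if d.hbd > rules.max_hbd:
        failed.append("HBD")
    if d.hba > rules.max_hba:
        failed.append("HBA")
    if d.rotatable_bonds > rules.max_rotatable:
        failed.append("ROTB")
    if rules.require_ring and d.sssr_ring_count == 0:
        failed.append("NO_RING")
    matched: tuple[str, ...] = ()
    if rules.exclude_reactive:
        matched = tuple(match_reactive_groups(m))
        if matched:
            failed.append("REACTIVE")
    return FilterVerdict(
        identifier=d.identifier,
        passed=not failed,
        failed_rules=tuple(failed),
        matched_reactive=matched,
    )


def filter_library(
    molecules: list[Molecule],
    rules: FragmentRules = DEFAULT_RULES,
) -> tuple[list[Molecule], pd.DataFrame]:
    """Partition a library into rule-compliant fragments and a verdict table.

    Order-preserving; the verdict table has one row per input molecule.
    Duplicate identifiers are rejected.
    """
    ids = [m.identifier for m in molecules]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate identifiers in library: {dupes}")
    passed: list[Molecule] = []
    rows = []
    for m in molecules:
        verdict = evaluate_fragment_rules(compute_descriptors(m), m, rules)
        if verdict.passed:
            passed.append(m)
        rows.append(
            {
                "identifier": verdict.identifier,
                "passed": verdict.passed,
                "failed_rules": ";".join(verdict.failed_rules),
                "matched_reactive": ";".join(verdict.matched_reactive),
            }
        )
    table = pd.DataFrame(rows, columns=["identifier", "passed", "failed_rules", "matched_reactive"])
    return passed, table
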