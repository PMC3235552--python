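"""Scaffold classification analysis (SCA): cyclicity and complexity.

Fragments are indexed by two scalar descriptors:

* **cyclicity** — the fraction of heavy atoms that are ring atoms, so a
  fully cyclic molecule (benzene, naphthalene, imidazole) scores exactly 1
  and an acyclic one scores 0.
* **complexity** — a size-and-shape score combining the smallest set of
  smallest rings, the heavy-atom count, the heavy-heavy bond count and the
  summed atomic numbers:

  ``raw = log2(1 + nSSSR) + log2(nHA) + log2(nBonds) + log2(sumZ)``

  (the bond term is dropped for a single-atom molecule), min–max rescaled
  into [0, 1] against anchors calibrated on the library under analysis.

Placing a two-target screen's hit classes in (cyclicity, complexity) space
is the core diagnostic: dual-activity fragments concentrate at high
complexity, selective ones below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import labels
from .chem import (
    Molecule,
    bond_count,
    heavy_atom_count,
    ring_atom_count,
    sssr_rings,
    sum_atomic_numbers,
)

__all__ = [
    "NormalizationSpec",
    "cyclicity",
    "complexity_raw",
    "complexity",
    "sca_table",
    "complexity_class_profile",
]


def cyclicity(m: Molecule) -> float:
    """Ring atoms over heavy atoms; 1.0 iff every heavy atom is in a ring."""
    n = heavy_atom_count(m)
    if n == 0:
        raise ValueError(f"{m.identifier}: molecule has no heavy atoms")
    return ring_atom_count(m) / n


def complexity_raw(m: Molecule) -> float:
    """Unnormalized complexity; strictly increasing in each ingredient."""
    n_rings = len(sssr_rings(m))
    n_ha = heavy_atom_count(m)
    n_bonds = bond_count(m)
    sum_z = sum_atomic_numbers(m)
    value = math.log2(1 + n_rings) + math.log2(n_ha) + math.log2(sum_z)
    if n_bonds > 0:
        value += math.log2(n_bonds)
    return value


@dataclass(frozen=True)
class NormalizationSpec:
    """Affine anchors mapping raw complexity onto [0, 1] (values clipped)."""

    raw_min: float
    raw_max: float

    def __post_init__(self) -> None:
        if not self.raw_max > self.raw_min:
            raise ValueError(
                f"degenerate normalization anchors: min={self.raw_min}, max={self.raw_max}"
            )

    @classmethod
    def from_library(cls, molecules: Iterable[Molecule]) -> "NormalizationSpec":
        raws = [complexity_raw(m) for m in molecules]
        if not raws:
            raise ValueError("cannot calibrate normalization on an empty library")
        return cls(raw_min=min(raws), raw_max=max(raws))

    def apply(self, raw: float) -> float:
        scaled = (raw - self.raw_min) / (self.raw_max - self.raw_min)
        return min(1.0, max(0.0, scaled))


def complexity(m: Molecule, norm: NormalizationSpec) -> float:
    """Normalized complexity in [0, 1]; preserves the raw-complexity ordering."""
    return norm.apply(complexity_raw(m))


def sca_table(
    molecules: Sequence[Molecule],
    class_labels: Mapping[str, str] | None = None,
    norm: NormalizationSpec | None = None,
) -> pd.DataFrame:
    """SCA coordinates for a library.

    Columns: ``identifier, cyclicity, complexity_raw, complexity, hit_class``.
    Unlisted molecules get the ``unlabeled`` class.  When ``norm`` is omitted
    the anchors are the raw min–max of the library itself and are recorded in
    ``DataFrame.attrs["normalization"]``.
    """
    cols = ["identifier", "cyclicity", "complexity_raw", "complexity", "hit_class"]
    if not molecules:
        return pd.DataFrame(columns=cols)
    if norm is None:
        norm = NormalizationSpec.from_library(molecules)
    class_labels = class_labels or {}
    unknown = sorted(set(class_labels.values()) - set(labels.ALL_LABELS))
    if unknown:
        raise ValueError(f"unknown hit-class labels: {unknown}")
    rows = []
    for m in molecules:
        raw = complexity_raw(m)
        rows.append(
            {
                "identifier": m.identifier,
                "cyclicity": cyclicity(m),
                "complexity_raw": raw,
                "complexity": norm.apply(raw),
                "hit_class": class_labels.get(m.identifier, labels.UNLABELED),
            }
        )
    table = pd.DataFrame(rows, columns=cols)
    table.attrs["normalization"] = {"raw_min": norm.raw_min, "raw_max": norm.raw_max}
    return table


def complexity_class_profile(points: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Per-class fraction of fragments at or above the complexity threshold.

    Returns one row per hit class present in ``points`` (empty classes are
    simply absent) with columns ``hit_class, n, n_at_or_above,
    frac_at_or_above, frac_below``; the two fractions sum to 1.
    """
    rows = []
    for hit_class, group in points.groupby("hit_class", sort=False):
        n = len(group)
        above = int((group["complexity"] >= threshold).sum())
        rows.append(
            {
                "hit_class": hit_class,
                "n": n,
                "n_at_or_above": above,
                "frac_at_or_above": above / n,
                "frac_below": (n - above) / n,
            }
        )
    return pd.DataFrame(
        rows, columns=["hit_class", "n", "n_at_or_above", "frac_at_or_above", "frac_below"]
    )
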