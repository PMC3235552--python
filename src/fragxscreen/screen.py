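"""Dual-target screen analysis: hit calling, classification and statistics.

A screen table holds one row per (fragment, target) with a percent effect at
the screening concentration and/or a pKi.  A fragment is a hit when its
percent effect reaches the target's cutoff (default 50%, the radioligand
displacement convention).  Two screens over the same library partition it
into A-selective, B-selective, dual and inactive fragments; the statistics
reported on that partition are the ones a fragment-screening campaign quotes:
hit rates, bidirectional hit-set overlap, fold selectivity from paired pKi
values, ligand efficiency, and per-class physicochemical distributions.

Reported percentages use half-up integer rounding; fold selectivity is
reported raw and rounded to one significant figure (10^2.7 ≈ 501 → "500").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import labels
from .chem import DESCRIPTOR_COLUMNS

__all__ = [
    "SCREEN_COLUMNS",
    "HitClassification",
    "call_hits",
    "classify",
    "hit_rate",
    "overlap_percentages",
    "fold_selectivity",
    "FoldSelectivity",
    "ligand_efficiency",
    "class_property_distributions",
]

SCREEN_COLUMNS = ["fragment_id", "target_id", "percent_effect", "pki", "is_hit"]

# gas constant in kcal·mol⁻¹·K⁻¹; RT·ln10 at 298.15 K ≈ 1.364 kcal/mol
GAS_CONSTANT_KCAL = 1.987204258640832e-3


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def call_hits(rows: pd.DataFrame, cutoff: float = 50.0) -> pd.DataFrame:
    """Assign hit flags: hit iff percent effect >= cutoff.

    ``rows`` needs columns ``fragment_id, target_id, percent_effect`` and may
    carry ``pki``.  Percent effects must lie in [0, 100]; rows with a missing
    percent effect keep a pre-existing ``is_hit`` flag if present, else False.
    """
    out = rows.copy()
    if "pki" not in out.columns:
        out["pki"] = np.nan
    effects = out["percent_effect"]
    known = effects.notna()
    bad = out.loc[known & ((effects < 0) | (effects > 100))]
    if len(bad):
        raise ValueError(
            f"percent effect outside [0, 100] for fragments: "
            f"{sorted(bad['fragment_id'].tolist())}"
        )
    if "is_hit" in out.columns:
        flags = out["is_hit"].fillna(False).astype(bool)
    else:
        flags = pd.Series(False, index=out.index)
    flags[known] = effects[known] >= cutoff
    out["is_hit"] = flags
    dupes = out.duplicated(subset=["fragment_id", "target_id"])
    if dupes.any():
        raise ValueError(
            f"duplicate (fragment, target) rows: "
            f"{sorted(out.loc[dupes, 'fragment_id'].tolist())}"
        )
    return out.loc[:, [c for c in SCREEN_COLUMNS if c in out.columns]]


@dataclass(frozen=True)
class HitClassification:
    """Partition of a library id set by the two screens' hit flags."""

    target_a: str
    target_b: str
    a_selective: frozenset[str]
    b_selective: frozenset[str]
    dual: frozenset[str]
    inactive: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.a_selective, self.b_selective, self.dual, self.inactive]
        total = sum(len(s) for s in sets)
        if total != len(frozenset().union(*sets)):
            raise ValueError("hit classes are not disjoint")

    @property
    def hits_a(self) -> frozenset[str]:
        return self.a_selective | self.dual

    @property
    def hits_b(self) -> frozenset[str]:
        return self.b_selective | self.dual

    @property
    def library_ids(self) -> frozenset[str]:
        return self.a_selective | self.b_selective | self.dual | self.inactive

    def label_of(self, fragment_id: str) -> str:
        if fragment_id in self.dual:
            return labels.DUAL
        if fragment_id in self.a_selective:
            return labels.A_SELECTIVE
        if fragment_id in self.b_selective:
            return labels.B_SELECTIVE
        if fragment_id in self.inactive:
            return labels.INACTIVE
        raise KeyError(fragment_id)

    def as_mapping(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for s, lab in (
            (self.a_selective, labels.A_SELECTIVE),
            (self.b_selective, labels.B_SELECTIVE),
            (self.dual, labels.DUAL),
            (self.inactive, labels.INACTIVE),
        ):
            for frag_id in s:
                mapping[frag_id] = lab
        return mapping

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.as_mapping().items())
        return pd.DataFrame(rows, columns=["fragment_id", "hit_class"])


def classify(
    screen_a: pd.DataFrame,
    screen_b: pd.DataFrame,
    library_ids: Iterable[str],
    target_a: str = "A",
    target_b: str = "B",
) -> HitClassification:
    """Partition the library into selective/dual/inactive from two screens.

    Every library fragment must appear in both screens; fragments covered by
    only one screen are reported by id.
    """
    lib = frozenset(library_ids)
    hits = {}
    for name, screen in (("A", screen_a), ("B", screen_b)):
        covered = frozenset(screen["fragment_id"])
        missing = lib - covered
        if missing:
            raise ValueError(
                f"fragments missing from screen {name}: {sorted(missing)[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        flagged = frozenset(screen.loc[screen["is_hit"].astype(bool), "fragment_id"])
        hits[name] = flagged & lib
    dual = hits["A"] & hits["B"]
    return HitClassification(
        target_a=target_a,
        target_b=target_b,
        a_selective=hits["A"] - dual,
        b_selective=hits["B"] - dual,
        dual=dual,
        inactive=lib - hits["A"] - hits["B"],
    )


def hit_rate(n_hits: int, n_library: int) -> int:
    """Hit rate as a half-up rounded integer percent."""
    if n_library <= 0:
        raise ValueError("library size must be positive")
    if not 0 <= n_hits <= n_library:
        raise ValueError(f"hit count {n_hits} outside [0, {n_library}]")
    return _round_half_up(100.0 * n_hits / n_library)


def overlap_percentages(c: HitClassification) -> tuple[int, int]:
    """(percent of B hits that are dual, percent of A hits that are dual).

    Both hit sets must be non-empty.  Rounding matches :func:`hit_rate`.
    """
    n_a, n_b, n_dual = len(c.hits_a), len(c.hits_b), len(c.dual)
    if n_a == 0 or n_b == 0:
        raise ValueError("overlap undefined: a target has no hits")
    return (
        _round_half_up(100.0 * n_dual / n_b),
        _round_half_up(100.0 * n_dual / n_a),
    )


@dataclass(frozen=True)
class FoldSelectivity:
    raw: float
    rounded: float  # one significant figure


def _round_1sf(x: float) -> float:
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    scale = 10.0 ** exponent
    return round(x / scale) * scale


def fold_selectivity(pki_hi: float, pki_lo: float) -> FoldSelectivity:
    """Fold selectivity 10^(pKi_hi − pKi_lo), raw and at 1 significant figure."""
    if pki_hi <= 0 or pki_lo <= 0:
        raise ValueError("pKi values must be positive")
    raw = 10.0 ** (pki_hi - pki_lo)
    return FoldSelectivity(raw=raw, rounded=_round_1sf(raw))


def ligand_efficiency(pki: float, heavy_atoms: int, temperature: float = 298.15) -> float:
    """Binding free-energy magnitude per heavy atom, kcal·mol⁻¹·HA⁻¹.

    LE = RT·ln(10)·pKi / HA; at 298.15 K the prefactor RT·ln10 is ≈1.364.
    """
    if heavy_atoms < 1:
        raise ValueError("heavy atom count must be >= 1")
    if pki < 0:
        raise ValueError("pKi must be non-negative")
    return GAS_CONSTANT_KCAL * temperature * math.log(10.0) * pki / heavy_atoms


_DEFAULT_HIST_DESCRIPTORS = [c for c in DESCRIPTOR_COLUMNS if c != "identifier"]


def class_property_distributions(
    classification: HitClassification,
    descriptors: pd.DataFrame,
    columns: Sequence[str] | None = None,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, dict[str, dict[str, dict]]]:
    """Per-class summary (n, mean, median) and fixed-bin histograms.

    Integer-valued descriptors are binned at unit width from 0; continuous
    ones (clogP) use ``n_bins`` equal-width bins over the library range.
    Returns ``(summary table, {descriptor: {class: histogram dict}})``.
    """
    columns = list(columns) if columns is not None else _DEFAULT_HIST_DESCRIPTORS
    table = descriptors.set_index("identifier")
    mapping = classification.as_mapping()
    missing = sorted(set(mapping) - set(table.index))
    if missing:
        raise ValueError(f"descriptors missing for fragments: {missing[:10]}")
    rows = []
    histograms: dict[str, dict[str, dict]] = {col: {} for col in columns}
    for hit_class in labels.HIT_CLASSES:
        ids = [i for i, lab in mapping.items() if lab == hit_class]
        if not ids:
            continue
        sub = table.loc[ids]
        for col in columns:
            values = sub[col].to_numpy(dtype=float)
            rows.append(
                {
                    "hit_class": hit_class,
                    "descriptor": col,
                    "n": len(values),
                    "mean": float(np.mean(values)),
                    "median": float(np.median(values)),
                }
            )
            if np.allclose(values, np.round(values)):
                hi = int(max(1, np.max(table[col].to_numpy(dtype=float))))
                edges = np.arange(0, hi + 2) - 0.5
            else:
                lo = float(table[col].min())
                hi = float(table[col].max())
                if lo == hi:
                    hi = lo + 1.0
                edges = np.linspace(lo, hi, n_bins + 1)
            counts, _ = np.histogram(values, bins=edges)
            histograms[col][hit_class] = {
                "bin_edges": [float(e) for e in edges],
                "counts": [int(c) for c in counts],
            }
    summary = pd.DataFrame(rows, columns=["hit_class", "descriptor", "n", "mean", "median"])
    return summary, histograms
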