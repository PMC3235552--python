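"""End-to-end analysis pipeline: filter → descriptors → SCA → fingerprints
→ screen analysis → report.

One call produces a self-contained report directory:

``verdicts.csv``        fragment-rule verdict per input molecule
``descriptors.csv``     physicochemical descriptor table (compliant fragments)
``sca.tsv``             cyclicity/complexity coordinates with hit classes
``fingerprints.json``   folded circular fingerprints (id → sorted bit list)
``classification.csv``  selective/dual/inactive partition
``summary.json``        hit rates, overlaps, diversity, complexity profile,
                        per-class property means, similarity profile, ligand
                        efficiency and fold-selectivity tables
``manifest.json``       tool version, config snapshot, input digests,
                        per-stage row counts, timestamp

``summary.json`` is a pure function of the inputs and configuration: rerun
on the same files, it is byte-identical (only the manifest timestamp moves).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__, labels
from .chem import Molecule, descriptor_table, read_smiles_file, write_descriptor_csv
from .filters import DEFAULT_RULES, FragmentRules, filter_library
from .fingerprints import (
    circular_fingerprint,
    endogenous_similarity_profile,
    pairwise_diversity,
    reference_ligands,
)
from .sca import complexity_class_profile, sca_table
from .screen import (
    call_hits,
    classify,
    class_property_distributions,
    fold_selectivity,
    hit_rate,
    ligand_efficiency,
    overlap_percentages,
)

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending records."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the full analysis; defaults are the published settings."""

    hit_cutoff_a: float = 50.0  # percent effect
    hit_cutoff_b: float = 50.0
    target_a: str = "A"
    target_b: str = "B"
    tc_threshold: float = 0.26
    complexity_threshold: float = 0.7
    fp_radius: int = 2
    fp_bits: int = 2048
    rules: FragmentRules = DEFAULT_RULES
    apply_filter: bool = True


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _read_screen(path: Path, target: str, cutoff: float) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"fragment_id", "target_id", "percent_effect"}
    missing = required - set(table.columns)
    if missing:
        raise PipelineError(f"screen {path}: missing columns {sorted(missing)}")
    table = table[table["target_id"].astype(str) == target]
    if table.empty:
        raise PipelineError(f"screen {path}: no rows for target {target!r}")
    table["fragment_id"] = table["fragment_id"].astype(str)
    try:
        return call_hits(table, cutoff=cutoff)
    except ValueError as exc:
        raise PipelineError(f"hit calling failed for target {target!r}: {exc}") from exc


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits) if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_full_analysis(
    library_path: str | Path,
    screen_a_path: str | Path,
    screen_b_path: str | Path,
    outdir: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
) -> Path:
    """Run the whole pipeline on a library and two screen tables.

    Returns the report directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    library_path = Path(library_path)
    screen_a_path = Path(screen_a_path)
    screen_b_path = Path(screen_b_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- stage: library -----------------------------------------------------
    try:
        molecules = read_smiles_file(library_path)
    except Exception as exc:
        raise PipelineError(f"stage library: {exc}") from exc
    counts["library_input"] = len(molecules)
    if not molecules:
        raise PipelineError("stage library: input library is empty")

    # --- stage: filter ------------------------------------------------------
    try:
        passed, verdicts = filter_library(molecules, config.rules)
    except ValueError as exc:
        raise PipelineError(f"stage filter: {exc}") from exc
    verdicts.to_csv(outdir / "verdicts.csv", index=False)
    fragments = passed if config.apply_filter else molecules
    counts["filter_passed"] = len(passed)
    if not fragments:
        raise PipelineError("stage filter: no rule-compliant fragments remain")

    # --- stage: descriptors -------------------------------------------------
    descriptors = descriptor_table(fragments)
    write_descriptor_csv(descriptors, outdir / "descriptors.csv")
    counts["descriptors"] = len(descriptors)

    # --- stage: screens + classification ------------------------------------
    screen_a = _read_screen(screen_a_path, config.target_a, config.hit_cutoff_a)
    screen_b = _read_screen(screen_b_path, config.target_b, config.hit_cutoff_b)
    lib_ids = [m.identifier for m in fragments]
    try:
        classification = classify(
            screen_a, screen_b, lib_ids, target_a=config.target_a, target_b=config.target_b
        )
    except ValueError as exc:
        raise PipelineError(f"stage classify: {exc}") from exc
    classification.to_frame().to_csv(outdir / "classification.csv", index=False)
    counts["screen_a_rows"] = len(screen_a)
    counts["screen_b_rows"] = len(screen_b)

    # --- stage: SCA ---------------------------------------------------------
    points = sca_table(fragments, classification.as_mapping())
    points.round(6).to_csv(outdir / "sca.tsv", sep="\t", index=False)
    counts["sca_points"] = len(points)
    profile = complexity_class_profile(points, threshold=config.complexity_threshold)

    # --- stage: fingerprints ------------------------------------------------
    fps = {
        m.identifier: circular_fingerprint(m, radius=config.fp_radius, n_bits=config.fp_bits)
        for m in fragments
    }
    with open(outdir / "fingerprints.json", "w") as fh:
        json.dump(
            {
                "n_bits": config.fp_bits,
                "radius": config.fp_radius,
                "fingerprints": {k: sorted(v.bits) for k, v in sorted(fps.items())},
            },
            fh,
            indent=None,
            separators=(",", ":"),
        )
    counts["fingerprints"] = len(fps)
    diversity_frac, n_pairs = pairwise_diversity(
        [fps[i] for i in lib_ids], threshold=config.tc_threshold
    )
    similarity = endogenous_similarity_profile(
        fps,
        classification.as_mapping(),
        references=reference_ligands(),
        threshold=config.tc_threshold,
        radius=config.fp_radius,
        n_bits=config.fp_bits,
    )

    # --- stage: screen statistics -------------------------------------------
    n_lib = len(lib_ids)
    n_hits_a, n_hits_b = len(classification.hits_a), len(classification.hits_b)
    overlaps = (
        overlap_percentages(classification)
        if n_hits_a and n_hits_b and classification.dual is not None
        else None
    )
    summary_dists, _hists = class_property_distributions(classification, descriptors)

    ha_by_id = dict(zip(descriptors["identifier"], descriptors["heavy_atoms"]))
    pki_by_target: dict[str, dict[str, float]] = {}
    le_rows = []
    for screen, target in ((screen_a, config.target_a), (screen_b, config.target_b)):
        known = screen[screen["pki"].notna()]
        pki_by_target[target] = dict(zip(known["fragment_id"], known["pki"]))
        for frag_id, pki in sorted(pki_by_target[target].items()):
            if frag_id in ha_by_id:
                le_rows.append(
                    {
                        "fragment_id": frag_id,
                        "target_id": target,
                        "pki": float(pki),
                        "heavy_atoms": int(ha_by_id[frag_id]),
                        "ligand_efficiency": ligand_efficiency(float(pki), int(ha_by_id[frag_id])),
                    }
                )
    selectivity_rows = []
    shared = sorted(set(pki_by_target[config.target_a]) & set(pki_by_target[config.target_b]))
    for frag_id in shared:
        pa = float(pki_by_target[config.target_a][frag_id])
        pb = float(pki_by_target[config.target_b][frag_id])
        hi_target = config.target_a if pa >= pb else config.target_b
        fs = fold_selectivity(max(pa, pb), min(pa, pb))
        selectivity_rows.append(
            {
                "fragment_id": frag_id,
                "preferred_target": hi_target,
                "pki_high": max(pa, pb),
                "pki_low": min(pa, pb),
                "fold_raw": fs.raw,
                "fold_rounded": fs.rounded,
            }
        )

    class_sizes = {
        labels.A_SELECTIVE: len(classification.a_selective),
        labels.B_SELECTIVE: len(classification.b_selective),
        labels.DUAL: len(classification.dual),
        labels.INACTIVE: len(classification.inactive),
    }
    summary = {
        "n_library": n_lib,
        "targets": {"A": config.target_a, "B": config.target_b},
        "class_sizes": class_sizes,
        "hit_counts": {config.target_a: n_hits_a, config.target_b: n_hits_b},
        "hit_rates_percent": {
            config.target_a: hit_rate(n_hits_a, n_lib),
            config.target_b: hit_rate(n_hits_b, n_lib),
        },
        "overlap_percent": None
        if overlaps is None
        else {
            f"{config.target_b}_hits_also_{config.target_a}": overlaps[0],
            f"{config.target_a}_hits_also_{config.target_b}": overlaps[1],
        },
        "diversity": {
            "tc_threshold": config.tc_threshold,
            "fraction_above": diversity_frac,
            "percent_above": 100.0 * diversity_frac,
            "n_pairs": n_pairs,
        },
        "complexity_profile": {
            "threshold": config.complexity_threshold,
            "per_class": profile.to_dict(orient="records"),
        },
        "class_property_means": summary_dists.to_dict(orient="records"),
        "reference_similarity": similarity.to_dict(orient="records"),
        "ligand_efficiency": le_rows,
        "fold_selectivity": selectivity_rows,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "tool": "fragxscreen",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k != "rules"
            },
            "rules": asdict(config.rules),
        },
        "inputs": {
            "library": {"path": str(library_path), "sha256": _sha256(library_path)},
            "screen_a": {"path": str(screen_a_path), "sha256": _sha256(screen_a_path)},
            "screen_b": {"path": str(screen_b_path), "sha256": _sha256(screen_b_path)},
        },
        "row_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
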