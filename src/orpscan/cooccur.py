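"""Retinal-biosynthesis capability and its co-occurrence with opsin classes.

A genome is scored for the five carotenoid/retinal pathway genes (crtE,
crtB, crtI produce lycopene; crtY cyclizes it to beta-carotene; brp
cleaves beta-carotene to retinal).  Presence of crtY AND brp is the
capability proxy: they catalyze the terminal, retinal-specific steps.
All five flags are reported so the implication "capable genomes carry the
full complement" stays checkable on any input.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

from .align import AlignmentParams, semiglobal_align
from .classify import OpsinCall
from .config import Thresholds
from .io import ProteinRecord, make_presence_absence_matrix
from .references import CRT_GENES, crt_panel
from .search import PRESETS, calibrate_reference_gate


@dataclass(frozen=True)
class PathwayComplement:
    """Per-genome presence flags for the five pathway genes."""

    genome_id: str
    crtY: bool
    brp: bool
    crtE: bool
    crtB: bool
    crtI: bool

    @property
    def retinal_capable(self) -> bool:
        return self.crtY and self.brp

    @property
    def partial_complement(self) -> bool:
        """Some pathway genes present but the terminal pair incomplete."""
        return not self.retinal_capable and any(
            getattr(self, g) for g in CRT_GENES
        )

    def flags(self) -> dict[str, bool]:
        return {g: getattr(self, g) for g in CRT_GENES}


@lru_cache(maxsize=16)
def _crt_gates(gap_open: int, gap_extend: int, n_decoys: int, seed: int):
    params = AlignmentParams(gap_open=gap_open, gap_extend=gap_extend)
    return {
        gene: calibrate_reference_gate(ref, params, n_decoys=n_decoys, seed=seed)
        for gene, ref in crt_panel().items()
    }


def detect_pathway(
    proteome: list[ProteinRecord],
    genome_id: str,
    thresholds: Thresholds | None = None,
    preset: str = "strict",
    crt_references: dict[str, ProteinRecord] | None = None,
) -> PathwayComplement:
    """Screen a proteome for the pathway genes at a decoy-calibrated gate.

    A gene is present when any proteome sequence's alignment score against
    its exemplar exceeds the exemplar's shuffled-decoy null at the preset's
    stringency (default ``strict``, the conservative-screen intent).
    """
    thresholds = thresholds or Thresholds()
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    k_sd = getattr(thresholds, PRESETS[preset])
    refs = crt_references if crt_references is not None else crt_panel()
    params = AlignmentParams(
        gap_open=thresholds.gap_open, gap_extend=thresholds.gap_extend
    )
    if crt_references is None:
        gates = _crt_gates(
            thresholds.gap_open, thresholds.gap_extend,
            thresholds.n_decoys, thresholds.calibration_seed,
        )
    else:
        gates = {
            gene: calibrate_reference_gate(
                ref, params, n_decoys=thresholds.n_decoys,
                seed=thresholds.calibration_seed,
            )
            for gene, ref in refs.items()
        }
    flags = {}
    for gene in CRT_GENES:
        ref = refs[gene]
        cutoff = gates[gene].cutoff(k_sd)
        flags[gene] = any(
            semiglobal_align(rec.sequence, ref.sequence, params).score >= cutoff
            for rec in proteome
        )
    return PathwayComplement(genome_id=genome_id, **flags)


def cooccurrence_table(
    calls_by_genome: dict[str, list[OpsinCall]],
    complements: list[PathwayComplement],
) -> tuple[pd.DataFrame, dict]:
    """Cross-tabulate opsin classes with pathway capability.

    Returns the genome x {opsin classes, crtY, brp} count matrix and a
    summary of genomes carrying ORPs but no canonical opsin, with the
    count of those additionally lacking retinal capability.
    """
    comp_by_genome = {c.genome_id: c for c in complements}
    unknown = set(calls_by_genome) - set(comp_by_genome)
    if unknown:
        raise ValueError(f"genomes without pathway complement: {sorted(unknown)}")

    rows: dict[str, dict[str, int]] = {}
    for genome in sorted(comp_by_genome):
        counts: dict[str, int] = {}
        for call in calls_by_genome.get(genome, []):
            label = call.class_label
            if label == "unassigned":
                continue
            counts[label] = counts.get(label, 0) + 1
        comp = comp_by_genome[genome]
        counts["crtY"] = int(comp.crtY)
        counts["brp"] = int(comp.brp)
        rows[genome] = counts
    matrix = make_presence_absence_matrix(rows)

    orp_cols = [c for c in matrix.columns if c.startswith("ORP")]
    canon_cols = ["BR", "BR2", "HR", "SRI", "SRII", "SR3", "MR"]
    orp_only = [
        g for g in matrix.index
        if matrix.loc[g, orp_cols].sum() > 0 and matrix.loc[g, canon_cols].sum() == 0
    ]
    lacking = [g for g in orp_only if not comp_by_genome[g].retinal_capable]
    lacking_both = [
        g for g in orp_only
        if not comp_by_genome[g].crtY and not comp_by_genome[g].brp
    ]
    summary = {
        "orp_only_genomes": orp_only,
        "n_orp_only": len(orp_only),
        "n_orp_only_lacking_capability": len(lacking),
        "n_orp_only_lacking_crtY_and_brp": len(lacking_both),
        "partial_complement_genomes": [
            c.genome_id for c in complements if c.partial_complement
        ],
    }
    return matrix, summary
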