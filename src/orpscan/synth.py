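"""Seed-deterministic synthetic fixtures with planted truth.

Every pipeline stage gets inputs whose correct answer is known by
construction: proteomes of family-backbone opsins with controlled edits
at the fingerprint positions, dipeptide-shuffled decoys, genome
annotations with planted neighborhood contexts, per-genome retinal
pathway complements, and absorbance spectra with optional retinal bands.

The generator emulates the statistical structure the screen assumes —
family backbones plus fixed fingerprint edits plus background
substitution noise — not phylogenetically realistic evolution (no indel
model).  The default configuration is the desk-scale study condition:
25 opsins (16 canonical across seven families, 3 group A + 6 group B
ORPs, the 1:2 A:B ratio of the motivating survey), 10 decoys, 10
genomes, background substitution rate 0.05, seed 7.

ORP edit plans (1-based reference numbering):

* group A: Schiff K216->R, W76->D, V108->M, Y174->L, W178->A; the
  signaling pair Y51/R72 is left unprotected (free to drift), D189/Y199
  protected.
* group B: Schiff K216->L, Y174->L, W178->G, F127->T; Y51/R72 and
  D189/Y199 all protected.

Fingerprint positions are re-imposed after background mutation, so the
planted signals are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GeneFeature, ProteinRecord, SpectrumRecord
from .references import (
    DEFAULT_SCHEMA,
    FAMILIES,
    crt_panel,
    crt_product,
    mutate,
    reference_by_id,
    reference_panel,
)
from .search import dipeptide_shuffle

ORP_A_EDITS = {216: "R", 76: "D", 108: "M", 174: "L", 178: "A"}
ORP_A_UNPROTECTED = {51, 72}
ORP_B_EDITS = {216: "L", 174: "L", 178: "G", 127: "T"}

DEFAULT_CLASS_COUNTS = {
    "BR": 3, "BR2": 2, "HR": 3, "SRI": 2, "SRII": 3, "SR3": 2, "MR": 1,
    "ORP_A": 3, "ORP_B": 6,
}

#: Neighborhood layouts planted per context category: (gene-rank offset,
#: product annotation) of the supporting genes.
CONTEXT_LAYOUTS = {
    "transducer_adjacent": ((1, "methyl-accepting chemotaxis protein"),),
    "taxis_operon_proximal": (
        (4, "chemotaxis protein CheW"),
        (6, "flagellin"),
    ),
    "stress_proximal": ((3, "heat shock protein Hsp20"),),
    "unlinked": (),
}

#: Category cycles over ORPs in generation order: group A loci sit next to
#: their transducers (as in the motivating survey, 15/16); group B spreads
#: over transducer, taxis-operon, stress and unlinked contexts.
CONTEXT_CYCLES = {
    "A": ("transducer_adjacent",),
    "B": (
        "transducer_adjacent", "taxis_operon_proximal", "stress_proximal",
        "unlinked", "taxis_operon_proximal", "stress_proximal",
    ),
}

_OPSIN_PRODUCTS = {
    "BR": "bacteriorhodopsin", "BR2": "bacteriorhodopsin-like protein 2",
    "HR": "halorhodopsin", "SRI": "sensory rhodopsin I",
    "SRII": "sensory rhodopsin II", "SR3": "sensory rhodopsin 3",
    "MR": "middle rhodopsin", "ORP_A": "opsin-related protein",
    "ORP_B": "opsin-related protein",
}


@dataclass(frozen=True)
class SpectrumPlan:
    """Parameters of one synthetic absorbance trace."""

    peak_nm: float | None = None
    peak_sigma_nm: float = 30.0
    peak_amplitude: float = 0.0
    noise_sd: float = 0.005
    a280_amplitude: float = 1.0
    a280_sigma_nm: float = 12.0
    baseline: float = 0.02

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")

    @property
    def holo(self) -> bool:
        return self.peak_nm is not None and self.peak_amplitude > 0


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic bundle (see module docstring)."""

    seed: int = 7
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_decoys: int = 10
    background_rate: float = 0.05
    n_genomes: int = 10
    genes_per_genome: int = 60
    orp_divergence: float = 0.15
    spectra_plans: dict[str, SpectrumPlan] = field(
        default_factory=lambda: {
            "holo_control": SpectrumPlan(peak_nm=550.0, peak_amplitude=0.3),
            "apo_orp": SpectrumPlan(),
        }
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_counts.values()) or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must lie in [0, 1)")


@dataclass(frozen=True)
class EntityPlan:
    entity_id: str
    kind: str  # opsin | decoy | crt
    family: str  # family label, "decoy", or crt gene name
    orp_group: str  # A | B | n/a
    genome_id: str
    context_category: str  # "" for non-ORP entities
    slot: int  # gene slot within the genome layout


def _genome_ids(cfg: SynthConfig) -> list[str]:
    return [f"genome{i + 1:02d}" for i in range(cfg.n_genomes)]


def plan_bundle(cfg: SynthConfig) -> tuple[list[EntityPlan], dict[str, set[str]]]:
    """Deterministic layout: entity -> genome/slot/context, genome -> pathway.

    Canonical opsins fill the front ~60% of genomes, ORPs the back ~60%
    (the overlap hosts mixed genomes).  Genomes with canonical opsins get
    the full five-gene pathway; ORP-only genomes get none, except the last
    one, which keeps brp alone (a partial complement).
    """
    genomes = _genome_ids(cfg)
    g = len(genomes)
    canon_zone = genomes[: max(1, math.ceil(0.6 * g))]
    orp_zone = genomes[min(g - 1, g - max(1, math.ceil(0.6 * g))):]

    entities: list[EntityPlan] = []
    canon_i = orp_i = 0
    orp_counters = {"A": 0, "B": 0}
    orp_slots_used: dict[str, int] = {g_: 0 for g_ in genomes}
    tail_used: dict[str, int] = {g_: 0 for g_ in genomes}

    def tail_slot(genome: str) -> int:
        tail_used[genome] += 1
        slot = cfg.genes_per_genome - tail_used[genome]
        if slot < 0:
            raise ValueError("genes_per_genome too small for planted entities")
        return slot

    for family in FAMILIES:
        for k in range(cfg.class_counts.get(family, 0)):
            genome = canon_zone[canon_i % len(canon_zone)]
            canon_i += 1
            entities.append(
                EntityPlan(
                    entity_id=f"{family}_{k + 1:02d}", kind="opsin",
                    family=family, orp_group="n/a", genome_id=genome,
                    context_category="", slot=tail_slot(genome),
                )
            )
    for group in ("A", "B"):
        cycle = CONTEXT_CYCLES[group]
        for k in range(cfg.class_counts.get(f"ORP_{group}", 0)):
            genome = orp_zone[orp_i % len(orp_zone)]
            orp_i += 1
            context = cycle[orp_counters[group] % len(cycle)]
            orp_counters[group] += 1
            slot = 15 + 25 * orp_slots_used[genome]
            orp_slots_used[genome] += 1
            if slot + 10 > cfg.genes_per_genome - 1:
                raise ValueError("genes_per_genome too small for planted ORP windows")
            entities.append(
                EntityPlan(
                    entity_id=f"ORP_{group}_{k + 1:02d}", kind="opsin",
                    family="ORP", orp_group=group, genome_id=genome,
                    context_category=context, slot=slot,
                )
            )
    for k in range(cfg.n_decoys):
        genome = genomes[k % g]
        entities.append(
            EntityPlan(
                entity_id=f"decoy_{k + 1:02d}", kind="decoy", family="decoy",
                orp_group="n/a", genome_id=genome, context_category="",
                slot=tail_slot(genome),
            )
        )

    has_canon = {e.genome_id for e in entities if e.kind == "opsin" and e.family != "ORP"}
    has_orp = {e.genome_id for e in entities if e.family == "ORP"}
    orp_only = sorted(has_orp - has_canon)
    pathway: dict[str, set[str]] = {}
    for genome in genomes:
        if genome in has_canon or genome not in has_orp:
            pathway[genome] = set(crt_panel())
        else:
            pathway[genome] = set()
    if orp_only:
        pathway[orp_only[-1]] = {"brp"}

    for genome in genomes:
        for gene in sorted(pathway[genome]):
            entities.append(
                EntityPlan(
                    entity_id=f"{genome}_{gene}", kind="crt", family=gene,
                    orp_group="n/a", genome_id=genome, context_category="",
                    slot=tail_slot(genome),
                )
            )

    # tail entities must stay clear of every planted ORP neighborhood
    orp_windows = {
        (e.genome_id, s)
        for e in entities if e.family == "ORP"
        for s in range(e.slot - 10, e.slot + 11)
    }
    for e in entities:
        if e.family != "ORP" and (e.genome_id, e.slot) in orp_windows:
            raise ValueError(
                "genes_per_genome too small: tail entities intrude into a "
                "planted ORP neighborhood"
            )
    return entities, pathway


def _orp_backbone(cfg: SynthConfig) -> str:
    """A common ORP ancestor: the SRII backbone diverged at a fixed rate,
    fingerprints protected (class edits come per sequence)."""
    rng = np.random.default_rng([cfg.seed, 500])
    srii = reference_by_id("SRII").sequence
    return mutate(srii, cfg.orp_divergence, rng, protected=set(DEFAULT_SCHEMA.positions))


def _planted_residues(family: str, group: str) -> dict[int, str]:
    base = dict(DEFAULT_SCHEMA.positions)
    if family != "ORP":
        return base
    if group == "A":
        for p in ORP_A_UNPROTECTED:
            base.pop(p)
        base.update(ORP_A_EDITS)
    elif group == "B":
        base.update(ORP_B_EDITS)
    else:
        raise ValueError(f"unknown ORP group {group!r}")
    return base


def _impose(seq: str, edits: dict[int, str]) -> str:
    chars = list(seq)
    for pos, aa in edits.items():
        chars[pos - 1] = aa
    return "".join(chars)


def generate_proteome(cfg: SynthConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Materialize the planned entities as protein records + truth table."""
    entities, pathway = plan_bundle(cfg)
    orp_backbone = _orp_backbone(cfg)
    records: list[ProteinRecord] = []
    rows = []
    for idx, ent in enumerate(entities):
        rng = np.random.default_rng([cfg.seed, 1000 + idx])
        if ent.kind == "opsin":
            backbone = (
                orp_backbone if ent.family == "ORP"
                else reference_by_id(ent.family).sequence
            )
            seq = mutate(backbone, cfg.background_rate, rng)
            seq = _impose(seq, _planted_residues(ent.family, ent.orp_group))
            product = _OPSIN_PRODUCTS[
                ent.family if ent.family != "ORP" else f"ORP_{ent.orp_group}"
            ]
        elif ent.kind == "decoy":
            k = int(ent.entity_id.split("_")[-1]) - 1
            src = reference_panel()[k % len(FAMILIES)].sequence
            seq = dipeptide_shuffle(src, rng)
            product = "hypothetical protein"
        else:  # crt
            seq = mutate(crt_panel()[ent.family].sequence, cfg.background_rate, rng)
            product = crt_product(ent.family)
        records.append(
            ProteinRecord(id=ent.entity_id, description=product, sequence=seq)
        )
        rows.append(
            {
                "entity_id": ent.entity_id,
                "kind": ent.kind,
                "family": ent.family,
                "orp_group": ent.orp_group,
                "class_label": (
                    f"ORP_{ent.orp_group}" if ent.family == "ORP" else ent.family
                ),
                "genome_id": ent.genome_id,
                "context_category": ent.context_category,
                "slot": ent.slot,
            }
        )
    truth = pd.DataFrame(rows)
    return records, truth


def genome_truth(cfg: SynthConfig) -> pd.DataFrame:
    """Per-genome planted pathway flags and derived capability."""
    _, pathway = plan_bundle(cfg)
    rows = []
    for genome, genes in sorted(pathway.items()):
        row = {"genome_id": genome}
        for gene in sorted(crt_panel()):
            row[gene] = gene in genes
        row["retinal_capable"] = "crtY" in genes and "brp" in genes
        rows.append(row)
    return pd.DataFrame(rows)


def generate_genome_annotation(
    cfg: SynthConfig,
) -> tuple[dict[str, list[GeneFeature]], pd.DataFrame]:
    """Linear gene layouts embedding every planted entity.

    Each genome is one contig of ``genes_per_genome`` 900 bp genes spaced
    1 kb apart.  Planted ORPs sit at interior slots with their context
    genes at the layout offsets; canonical opsins, decoys and crt genes
    occupy the contig tail, far from any planted neighborhood.
    """
    entities, _ = plan_bundle(cfg)
    truth_rows = []
    features: dict[str, list[GeneFeature]] = {g: [] for g in _genome_ids(cfg)}
    planted: dict[str, dict[int, tuple[str, str]]] = {
        g: {} for g in _genome_ids(cfg)
    }  # genome -> slot -> (locus_id, product)

    for ent in entities:
        if ent.kind == "crt":
            product = crt_product(ent.family)
        elif ent.kind == "decoy":
            product = "hypothetical protein"
        else:
            product = _OPSIN_PRODUCTS[
                ent.family if ent.family != "ORP" else f"ORP_{ent.orp_group}"
            ]
        planted[ent.genome_id][ent.slot] = (ent.entity_id, product)
        if ent.family == "ORP":
            for offset, product in CONTEXT_LAYOUTS[ent.context_category]:
                slot = ent.slot + offset
                planted[ent.genome_id][slot] = (
                    f"{ent.genome_id}_n{slot:03d}", product
                )
            truth_rows.append(
                {
                    "entity_id": ent.entity_id,
                    "genome_id": ent.genome_id,
                    "context_category": ent.context_category,
                }
            )

    for genome in _genome_ids(cfg):
        contig = f"{genome}_c1"
        for slot in range(cfg.genes_per_genome):
            start = 200 + 1000 * slot
            locus, product = planted[genome].get(
                slot, (f"{genome}_f{slot:03d}", "hypothetical protein")
            )
            features[genome].append(
                GeneFeature(
                    genome_id=genome, contig=contig, start=start,
                    end=start + 900, strand="+", locus_id=locus, product=product,
                )
            )
    return features, pd.DataFrame(truth_rows)


def generate_spectrum(
    plan: SpectrumPlan, seed: int = 0
) -> SpectrumRecord:
    """One synthetic trace on the 250-800 nm grid at 2 nm steps."""
    rng = np.random.default_rng([seed, 3000])
    wl = np.arange(250.0, 801.0, 2.0)
    ab = np.full_like(wl, plan.baseline)
    ab += plan.a280_amplitude * np.exp(
        -0.5 * ((wl - 280.0) / plan.a280_sigma_nm) ** 2
    )
    if plan.peak_nm is not None and plan.peak_amplitude > 0:
        ab += plan.peak_amplitude * np.exp(
            -0.5 * ((wl - plan.peak_nm) / plan.peak_sigma_nm) ** 2
        )
    ab += rng.normal(0.0, plan.noise_sd, size=wl.size)
    return SpectrumRecord(wavelengths=wl, absorbances=ab)


def generate_bundle(cfg: SynthConfig):
    """Everything at once: records, per-genome features, truth tables, spectra."""
    records, truth = generate_proteome(cfg)
    features, context_truth = generate_genome_annotation(cfg)
    spectra = {
        name: generate_spectrum(plan, seed=cfg.seed + i)
        for i, (name, plan) in enumerate(sorted(cfg.spectra_plans.items()))
    }
    spectra_truth = pd.DataFrame(
        [
            {"sample": name, "holo": plan.holo}
            for name, plan in sorted(cfg.spectra_plans.items())
        ]
    )
    return {
        "records": records,
        "proteome_truth": truth,
        "features": features,
        "context_truth": context_truth,
        "genome_truth": genome_truth(cfg),
        "spectra": spectra,
        "spectra_truth": spectra_truth,
    }


def proteomes_by_genome(
    records: list[ProteinRecord], truth: pd.DataFrame
) -> dict[str, list[ProteinRecord]]:
    by_id = {r.id: r for r in records}
    out: dict[str, list[ProteinRecord]] = {}
    for _, row in truth.iterrows():
        out.setdefault(row["genome_id"], []).append(by_id[row["entity_id"]])
    return out
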