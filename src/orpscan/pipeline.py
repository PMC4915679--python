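"""Full screen orchestration: search -> anchor -> classify -> phylo ->
context -> co-occurrence, with a report bundle of tables and counts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import AlignmentParams
from .anchor import AnchorError, anchor_to_reference, extract_fingerprint
from .classify import OpsinCall, assign_family, calls_table, conservation_report
from .config import Thresholds
from .context import ContextVocabulary, classify_locus
from .cooccur import PathwayComplement, cooccurrence_table, detect_pathway
from .io import GeneFeature, ProteinRecord, write_itol_binary, write_matrix_tsv
from .phylo import distance_matrix, is_monophyletic, neighbor_joining, to_newick
from .references import DEFAULT_SCHEMA, reference_by_id
from .search import HomologHit, search_proteome

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """Everything one screen produces."""

    calls: list[OpsinCall]
    calls_by_genome: dict[str, list[OpsinCall]]
    fingerprints: pd.DataFrame
    conservation: pd.DataFrame
    context: pd.DataFrame
    complements: list[PathwayComplement]
    matrix: pd.DataFrame
    summary: dict
    newick: str | None = None
    errors: dict[str, str] = field(default_factory=dict)


def _anchored_msa(
    hits: list[HomologHit], thresholds: Thresholds, params: AlignmentParams
) -> dict[str, str]:
    """Reference-anchored pseudo-alignment: each hit's residues written into
    the reference's columns (insertions relative to the reference dropped).
    Desk-scale stand-in for a de novo multiple alignment."""
    ref = reference_by_id(DEFAULT_SCHEMA.reference_id)
    ncols = len(ref.sequence)
    rows = {}
    for hit in hits:
        rmap = anchor_to_reference(
            hit.query, DEFAULT_SCHEMA, params, thresholds.anchor_min_identity
        )
        chars = []
        for p in range(1, ncols + 1):
            q = rmap.mapping.get(p)
            chars.append("-" if q is None else hit.query.sequence[q - 1])
        rows[hit.query.id] = "".join(chars)
    return rows


def run_screen(
    proteomes: dict[str, list[ProteinRecord]],
    gffs: dict[str, list[GeneFeature]] | None = None,
    thresholds: Thresholds | None = None,
    vocab: ContextVocabulary | None = None,
    preset: str = "standard",
    do_phylo: bool = True,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Run the whole screen over per-genome proteomes.

    ``gffs`` maps genome id to its gene features; genomes without
    annotation skip the context stage.  Per-genome failures are isolated
    and reported in ``bundle.errors``; an empty proteome set is an error.
    """
    if not proteomes:
        raise ValueError("no proteomes supplied")
    thresholds = thresholds or Thresholds()
    params = AlignmentParams(
        gap_open=thresholds.gap_open, gap_extend=thresholds.gap_extend
    )
    gffs = gffs or {}
    logger.info(
        "screen over %d genomes (preset=%s, min_identity=%.2f, min_coverage=%.2f)",
        len(proteomes), preset, thresholds.min_identity, thresholds.min_coverage,
    )

    calls_by_genome: dict[str, list[OpsinCall]] = {}
    all_hits: list[HomologHit] = []
    complements: list[PathwayComplement] = []
    context_rows = []
    errors: dict[str, str] = {}

    for genome_id in sorted(proteomes):
        try:
            proteome = proteomes[genome_id]
            hits = search_proteome(
                proteome, params=params, thresholds=thresholds, preset=preset
            )
            genome_calls = []
            for hit in hits:
                try:
                    rmap = anchor_to_reference(
                        hit.query, DEFAULT_SCHEMA, params, thresholds.anchor_min_identity
                    )
                except AnchorError as exc:
                    logger.warning("%s: %s", genome_id, exc)
                    continue
                fp = extract_fingerprint(hit.query, rmap, DEFAULT_SCHEMA)
                call = assign_family(
                    hit, fp, DEFAULT_SCHEMA, thresholds, genome_id=genome_id
                )
                genome_calls.append(call)
                all_hits.append(hit)
            features = gffs.get(genome_id)
            if features is not None:
                labelled = []
                for call in genome_calls:
                    if call.family != "ORP":
                        labelled.append(call)
                        continue
                    label = classify_locus(
                        features, call.query_id, vocab, thresholds
                    )
                    labelled.append(call.with_context(label.category))
                    context_rows.append(
                        {
                            "genome_id": genome_id,
                            "locus_id": call.query_id,
                            "orp_group": call.orp_group,
                            "category": label.category,
                            "supporting_loci": ";".join(label.supporting_loci),
                            "ranks": ";".join(map(str, label.ranks)),
                            "co_oriented": label.co_oriented,
                        }
                    )
                genome_calls = labelled
            calls_by_genome[genome_id] = genome_calls
            complements.append(
                detect_pathway(proteome, genome_id, thresholds, preset="strict")
            )
        except Exception as exc:  # noqa: BLE001 - per-genome isolation
            logger.error("genome %s failed: %s", genome_id, exc)
            errors[genome_id] = str(exc)

    calls = [c for calls_ in calls_by_genome.values() for c in calls_]
    if not calls:
        raise ValueError("no opsin homologs recovered from any proteome")
    fingerprints = calls_table(calls)
    conservation = conservation_report(calls)
    matrix, cooccur_summary = cooccurrence_table(calls_by_genome, complements)

    newick = None
    orp_monophyletic = None
    if do_phylo and len(all_hits) >= 3:
        msa = _anchored_msa(all_hits, thresholds, params)
        dm = distance_matrix(msa, correction="p")
        tree = neighbor_joining(dm)
        newick = to_newick(tree)
        orp_ids = {c.query_id for c in calls if c.family == "ORP"}
        if 1 < len(orp_ids) < len(msa):
            orp_monophyletic = is_monophyletic(tree, orp_ids)

    n_orp = sum(c.family == "ORP" for c in calls)
    n_a = sum(c.orp_group == "A" for c in calls)
    n_b = sum(c.orp_group == "B" for c in calls)
    summary = {
        "n_genomes": len(proteomes),
        "n_opsins": len(calls),
        "n_canonical": sum(c.schiff_status == "canonical" for c in calls),
        "n_orp": n_orp,
        "n_group_a": n_a,
        "n_group_b": n_b,
        "n_orp_unassigned": n_orp - n_a - n_b,
        "n_schiff_unassigned": sum(c.schiff_status == "unassigned" for c in calls),
        "transducer_adjacent": {
            g: sum(
                c.orp_group == g and c.context_category == "transducer_adjacent"
                for c in calls
            )
            for g in ("A", "B")
        },
        "orp_monophyletic": orp_monophyletic,
        **cooccur_summary,
        "thresholds": {
            "preset": preset,
            "min_identity": thresholds.min_identity,
            "min_coverage": thresholds.min_coverage,
            "adjacency_rank": thresholds.adjacency_rank,
            "proximity_rank": thresholds.proximity_rank,
        },
    }

    bundle = ReportBundle(
        calls=calls,
        calls_by_genome=calls_by_genome,
        fingerprints=fingerprints,
        conservation=conservation,
        context=pd.DataFrame(context_rows),
        complements=complements,
        matrix=matrix,
        summary=summary,
        newick=newick,
        errors=errors,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.fingerprints.to_csv(out / "calls.tsv", sep="\t", index=False)
    bundle.conservation.to_csv(out / "conservation.tsv", sep="\t", index=False)
    bundle.context.to_csv(out / "context.tsv", sep="\t", index=False)
    write_matrix_tsv(bundle.matrix, out / "presence_absence.tsv")
    write_itol_binary(bundle.matrix, out / "itol_presence_absence.txt")
    if bundle.newick:
        (out / "opsins.nwk").write_text(bundle.newick + "\n")
    (out / "summary.json").write_text(json.dumps(bundle.summary, indent=2) + "\n")
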