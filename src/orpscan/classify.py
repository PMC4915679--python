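"""Family assignment, the Schiff-base screen, and ORP grouping.

The defining test is read at the Schiff-base column: a lysine there makes
a canonical opsin; any other residue makes an opsin-related protein (ORP);
a gap (truncation, not substitution) leaves the sequence unassigned.
ORPs split into group A (arginine at the Schiff column) and group B (a
hydrophobic residue, leucine most commonly).  Canonical sequences take
the family label of their nearest reference by alignment score — a
desk-scale stand-in for clade affiliation in a full phylogeny, with the
neighbor-joining monophyly check as corroboration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .anchor import GAP, Fingerprint
from .config import Thresholds
from .references import DEFAULT_SCHEMA, FingerprintSchema
from .search import HomologHit

FAMILY_LABELS = ("BR", "BR2", "HR", "SRI", "SRII", "SR3", "MR", "ORP")


@dataclass(frozen=True)
class OpsinCall:
    """One classified opsin homolog."""

    query_id: str
    family: str
    orp_group: str  # "A" | "B" | "unassigned" | "n/a"
    fingerprint: Fingerprint
    nearest_reference_id: str
    score: float
    schiff_status: str = "canonical"  # "canonical" | "ORP" | "unassigned"
    genome_id: str = ""
    context_category: str = ""

    def __post_init__(self) -> None:
        if (self.orp_group != "n/a") != (self.family == "ORP"):
            raise ValueError("orp_group must be n/a exactly when family is not ORP")
        if (self.schiff_status == "ORP") != (self.family == "ORP"):
            raise ValueError("schiff_status ORP must coincide with family ORP")

    @property
    def class_label(self) -> str:
        """Column label used in reports: family, with ORP split by group;
        Schiff-column truncations are reported as unassigned."""
        if self.schiff_status == "unassigned":
            return "unassigned"
        if self.family != "ORP":
            return self.family
        return f"ORP_{self.orp_group}" if self.orp_group in ("A", "B") else "ORP_unassigned"

    def with_context(self, category: str) -> "OpsinCall":
        return replace(self, context_category=category)


def schiff_base_test(fp: Fingerprint, schema: FingerprintSchema = DEFAULT_SCHEMA) -> str:
    """Classify the Schiff-base column: K -> canonical, gap -> unassigned,
    anything else -> ORP."""
    residue = fp[schema.schiff_position]
    if residue == "K":
        return "canonical"
    if residue == GAP:
        return "unassigned"
    return "ORP"


def orp_group(
    fp: Fingerprint,
    schema: FingerprintSchema = DEFAULT_SCHEMA,
    hydrophobic_set: str = Thresholds.hydrophobic_set,
) -> str:
    """Group an ORP by its Schiff-column residue: R -> A, hydrophobic -> B."""
    outcome = schiff_base_test(fp, schema)
    if outcome != "ORP":
        raise ValueError(
            f"orp_group is only defined for ORP fingerprints (got {outcome})"
        )
    residue = fp[schema.schiff_position]
    if residue == "R":
        return "A"
    if residue in hydrophobic_set:
        return "B"
    return "unassigned"


def assign_family(
    hit: HomologHit,
    fp: Fingerprint,
    schema: FingerprintSchema = DEFAULT_SCHEMA,
    thresholds: Thresholds | None = None,
    genome_id: str = "",
) -> OpsinCall:
    """Full call for one domain-gated hit."""
    thresholds = thresholds or Thresholds()
    outcome = schiff_base_test(fp, schema)
    if outcome == "ORP":
        family = "ORP"
        group = orp_group(fp, schema, thresholds.hydrophobic_set)
    else:
        # canonical, or truncated at the Schiff column (unassigned): the
        # nearest reference still carries the best family hypothesis
        family = hit.best_reference_id
        group = "n/a"
    return OpsinCall(
        query_id=hit.query.id,
        family=family,
        orp_group=group,
        fingerprint=fp,
        nearest_reference_id=hit.best_reference_id,
        score=hit.alignment.score,
        schiff_status=outcome,
        genome_id=genome_id,
    )


def conservation_report(
    calls: list[OpsinCall], schema: FingerprintSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Per class label and schema position: modal residue, conservation
    fraction, and class size.  Mirrors a per-family conservation table."""
    if not calls:
        raise ValueError("conservation report needs at least one call")
    rows = []
    by_class: dict[str, list[OpsinCall]] = {}
    for call in calls:
        by_class.setdefault(call.class_label, []).append(call)
    for label in sorted(by_class):
        members = by_class[label]
        for pos in schema.ordered_positions:
            residues = [c.fingerprint[pos] for c in members]
            modal, count = Counter(residues).most_common(1)[0]
            rows.append(
                {
                    "class_label": label,
                    "position": pos,
                    "role": schema.roles[pos],
                    "modal_residue": modal,
                    "conservation_fraction": count / len(residues),
                    "n": len(residues),
                }
            )
    return pd.DataFrame(rows)


def calls_table(calls: list[OpsinCall], schema: FingerprintSchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """One row per call, fingerprint spread over per-position columns."""
    rows = []
    for c in calls:
        row = {
            "query_id": c.query_id,
            "genome_id": c.genome_id,
            "family": c.family,
            "orp_group": c.orp_group,
            "schiff_status": c.schiff_status,
            "class_label": c.class_label,
            "nearest_reference": c.nearest_reference_id,
            "score": c.score,
            "context_category": c.context_category,
        }
        for pos in schema.ordered_positions:
            row[f"pos{pos}"] = c.fingerprint[pos]
        rows.append(row)
    return pd.DataFrame(rows)
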