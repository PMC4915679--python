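"""Reference-anchored residue numbering and fingerprint extraction.

A query is aligned to the numbering reference (the packaged SRII exemplar
by default) with free end gaps; each reference position then maps to the
query position sharing its alignment column, or to a gap.  Fingerprints
read the query residues at the functional position set of the schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentParams, semiglobal_align
from .io import ProteinRecord
from .references import DEFAULT_SCHEMA, FingerprintSchema, reference_by_id

GAP = "-"


class AnchorError(ValueError):
    """Raised when a query cannot be anchored to the reference numbering."""


@dataclass(frozen=True)
class ResidueMap:
    """Mapping from 1-based reference positions to 1-based query positions.

    ``mapping[p]`` is ``None`` where reference position ``p`` aligns to a
    gap in the query.  Over non-gap entries the mapping is strictly
    increasing (alignment columns are monotone).
    """

    query_id: str
    reference_id: str
    mapping: dict[int, int | None] = field(repr=False)
    identity: float = 0.0

    def __post_init__(self) -> None:
        present = [q for q in self.mapping.values() if q is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            raise ValueError("residue map must be monotone increasing")


@dataclass(frozen=True)
class Fingerprint:
    """Observed query residues at the schema positions (GAP = '-')."""

    query_id: str
    residues: dict[int, str]

    def __getitem__(self, position: int) -> str:
        return self.residues[position]

    @property
    def schiff_residue(self) -> str:
        return self.residues[DEFAULT_SCHEMA.schiff_position]


def anchor_to_reference(
    query: ProteinRecord,
    schema: FingerprintSchema = DEFAULT_SCHEMA,
    params: AlignmentParams | None = None,
    min_identity: float = 0.15,
    reference: ProteinRecord | None = None,
) -> ResidueMap:
    """Map the reference numbering onto ``query`` via pairwise alignment."""
    ref = reference if reference is not None else reference_by_id(schema.reference_id)
    aln = semiglobal_align(
        query.sequence, ref.sequence, params, query_id=query.id, subject_id=ref.id
    )
    # identity for anchorability is global: matches over the shorter
    # sequence, so a tiny well-matching island cannot anchor junk
    matches = sum(
        a == b != GAP for a, b in zip(aln.aligned_query, aln.aligned_subject)
    )
    identity = matches / min(len(query.sequence), len(ref.sequence))
    if identity < min_identity:
        raise AnchorError(
            f"unanchorable: {query.id} aligns to {ref.id} at "
            f"{identity:.0%} global identity (< {min_identity:.0%})"
        )
    mapping: dict[int, int | None] = {}
    qpos = rpos = 0
    for qc, rc in zip(aln.aligned_query, aln.aligned_subject):
        if qc != GAP:
            qpos += 1
        if rc != GAP:
            rpos += 1
            mapping[rpos] = qpos if qc != GAP else None
    for p in range(rpos + 1, len(ref.sequence) + 1):  # trailing reference gap
        mapping[p] = None
    return ResidueMap(
        query_id=query.id, reference_id=ref.id, mapping=mapping, identity=identity
    )


def extract_fingerprint(
    query: ProteinRecord,
    residue_map: ResidueMap,
    schema: FingerprintSchema = DEFAULT_SCHEMA,
) -> Fingerprint:
    """Read the query residues at the schema's positions through the map."""
    residues: dict[int, str] = {}
    for pos in schema.ordered_positions:
        q = residue_map.mapping.get(pos)
        residues[pos] = GAP if q is None else query.sequence[q - 1]
    return Fingerprint(query_id=query.id, residues=residues)


def fingerprint_query(
    query: ProteinRecord,
    schema: FingerprintSchema = DEFAULT_SCHEMA,
    params: AlignmentParams | None = None,
    min_identity: float = 0.15,
) -> Fingerprint:
    """Convenience: anchor then extract in one step."""
    rmap = anchor_to_reference(query, schema, params, min_identity)
    return extract_fingerprint(query, rmap, schema)
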