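"""Fingerprint one sequence and classify it.

Takes the packaged SRII exemplar, swaps its Schiff-base lysine for
arginine (the group A ORP signature), and walks it through search,
anchoring, fingerprint extraction and classification.
"""

from orpscan.anchor import fingerprint_query
from orpscan.classify import assign_family
from orpscan.io import ProteinRecord
from orpscan.references import DEFAULT_SCHEMA, reference_by_id
from orpscan.search import search_proteome

ref = reference_by_id("SRII")
pos = DEFAULT_SCHEMA.schiff_position
mutant = ProteinRecord(
    id="srii_K216R",
    description="SRII with the Schiff-base lysine replaced by arginine",
    sequence=ref.sequence[: pos - 1] + "R" + ref.sequence[pos:],
)

(hit,) = search_proteome([mutant])
fp = fingerprint_query(mutant)
call = assign_family(hit, fp)

print("fingerprint (reference numbering -> observed residue):")
for p in DEFAULT_SCHEMA.ordered_positions:
    role = DEFAULT_SCHEMA.roles[p]
    print(f"  {p:>3} ({role:14s}): {fp[p]}  [canonical {DEFAULT_SCHEMA.positions[p]}]")
print(f"\nfamily: {call.family}, ORP group: {call.orp_group} -> {call.class_label}")
# A single K->R at position 216 flips the call from canonical SRII to a
# group A opsin-related protein; every other fingerprint cell is intact.
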