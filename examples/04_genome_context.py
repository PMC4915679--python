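"""Classify the gene-neighborhood context of an ORP locus.

Builds a small annotated contig with an ORP next to a methyl-accepting
chemotaxis transducer and another ORP near a chemotaxis/flagellar gene
block, then applies the context rules.
"""

from orpscan.context import classify_locus
from orpscan.io import GeneFeature

products = {
    0: "hypothetical protein",
    1: "opsin-related protein",            # orp1: transducer at rank +1
    2: "methyl-accepting chemotaxis protein",
    8: "opsin-related protein",            # orp2: CheW at +3, flagellin at +5
    11: "chemotaxis protein CheW",
    13: "flagellin",
}
features = [
    GeneFeature(
        genome_id="demo", contig="c1", start=200 + 1000 * i, end=1100 + 1000 * i,
        strand="+", locus_id=f"orp{1 if i == 1 else 2}" if i in (1, 8) else f"g{i}",
        product=products.get(i, "hypothetical protein"),
    )
    for i in range(15)
]

for locus in ("orp1", "orp2"):
    label = classify_locus(features, locus)
    print(f"{locus}: {label.category}  supporting={label.supporting_loci} ranks={label.ranks}")
# orp1 is transducer_adjacent (an MCP gene one step away, the hallmark of
# sensory opsins co-operonic with their transducers); orp2 has two
# taxis-operon genes within ten ranks and no adjacent transducer, so it
# is taxis_operon_proximal.
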