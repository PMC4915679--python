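import pytest

from orpscan.context import (
    ContextVocabulary,
    Neighbor,
    classify_context,
    classify_locus,
    neighborhood,
)
from orpscan.io import GeneFeature


def _contig(products, contig="c1", genome="g", flip=False, offset=0):
    """Build a linear contig; products[i] annotates gene i."""
    n = len(products)
    feats = []
    for i, product in enumerate(products):
        start = offset + 1000 * (n - 1 - i if flip else i)
        feats.append(
            GeneFeature(
                genome_id=genome, contig=contig, start=start, end=start + 900,
                strand="-" if flip else "+", locus_id=f"g{i}", product=product,
            )
        )
    return sorted(feats, key=lambda f: f.start)


VOCAB = ContextVocabulary.default()


def test_default_vocabulary_priorities():
    assert VOCAB.categorize("methyl-accepting chemotaxis protein") == "transducer"
    assert VOCAB.categorize("chemotaxis protein CheW") == "taxis_operon"
    assert VOCAB.categorize("heat shock protein Hsp20") == "stress"
    assert VOCAB.categorize("hypothetical protein") is None


def test_neighborhood_window_and_boundaries():
    feats = _contig(["x"] * 5)
    nbs = neighborhood(feats, "g2", window_genes=2)
    assert [nb.rank for nb in nbs] == [-2, -1, 1, 2]
    # target at contig start: only downstream neighbors
    nbs = neighborhood(feats, "g0", window_genes=2)
    assert [nb.rank for nb in nbs] == [1, 2]
    assert neighborhood(feats, "g2", window_genes=0) == []
    with pytest.raises(ValueError, match="not found"):
        neighborhood(feats, "missing", 2)


def test_transducer_adjacent_rule():
    feats = _contig(["x", "opsin-related protein", "methyl-accepting chemotaxis protein"])
    label = classify_locus(feats, "g1")
    assert label.category == "transducer_adjacent"
    assert label.supporting_loci == ("g2",)
    assert label.ranks == (1,)


def test_taxis_operon_needs_two_genes_and_no_adjacent_transducer():
    products = ["orp"] + ["x"] * 10
    products[4] = "chemotaxis protein CheW"
    products[6] = "flagellin"
    label = classify_locus(_contig(products), "g0")
    assert label.category == "taxis_operon_proximal"
    assert set(label.supporting_loci) == {"g4", "g6"}


def test_single_taxis_gene_is_not_enough_but_stress_is():
    products = ["orp"] + ["x"] * 10
    products[4] = "chemotaxis protein CheW"
    products[3] = "heat shock protein"
    label = classify_locus(_contig(products), "g0")
    assert label.category == "stress_proximal"


def test_unlinked_when_nothing_categorized_within_window():
    products = ["orp"] + ["x"] * 12
    products[11] = "flagellin"  # rank 11 > proximity_rank 10
    products[12] = "chemotaxis protein CheW"
    label = classify_locus(_contig(products), "g0")
    assert label.category == "unlinked"
    # widening the window flips it to taxis-linked, never the other way
    nbs = neighborhood(_contig(products), "g0", window_genes=12)
    wide = classify_context(nbs, VOCAB, proximity_rank=12)
    assert wide.category == "taxis_operon_proximal"


def test_label_invariant_under_translation_and_strand_flip():
    products = ["x", "orp", "methyl-accepting chemotaxis protein", "x"]
    base = classify_locus(_contig(products), "g1")
    shifted = classify_locus(_contig(products, offset=123456), "g1")
    flipped = classify_locus(_contig(products, flip=True), "g1")
    assert base.category == shifted.category == flipped.category == "transducer_adjacent"


def test_transducer_beyond_adjacency_does_not_make_adjacent():
    products = ["orp", "x", "methyl-accepting chemotaxis protein"]
    nbs = neighborhood(_contig(products), "g0", 10)
    assert classify_context(nbs, VOCAB, adjacency_rank=1).category != "transducer_adjacent"
    assert classify_context(nbs, VOCAB, adjacency_rank=2).category == "transducer_adjacent"


def test_context_label_validation():
    from orpscan.context import ContextLabel

    with pytest.raises(ValueError, match="unknown context label"):
        ContextLabel(category="nearby")
    with pytest.raises(ValueError, match="non-zero"):
        ContextLabel(category="transducer_adjacent", ranks=(0,))
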