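"""Gene-neighborhood context of ORP loci.

Sensory rhodopsins are typically co-operonic with their methyl-accepting
chemotaxis (HAMP/MCP) signal transducers, so the neighborhood of each ORP
gene is scanned for transducers, chemotaxis/flagellar operon genes, and
stress-response genes.  Distances are in gene ranks (number of genes
away on the same contig), not base pairs: the labels must be invariant
under coordinate translation and whole-contig strand flips.

Rules, applied in priority order:

1. ``transducer_adjacent`` — a transducer within ``adjacency_rank`` (1).
2. ``taxis_operon_proximal`` — at least ``taxis_min_neighbors`` (2)
   chemotaxis/flagellar genes within ``proximity_rank`` (10).
3. ``stress_proximal`` — at least one stress gene within the same window.
4. ``unlinked`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .config import Thresholds
from .io import GeneFeature

CATEGORIES = ("transducer", "taxis_operon", "stress")
LABELS = ("transducer_adjacent", "taxis_operon_proximal", "stress_proximal", "unlinked")


@dataclass(frozen=True)
class ContextVocabulary:
    """Ordered keyword lists mapping product strings to categories.

    Matching is case-insensitive substring, first category wins in the
    priority order transducer > taxis_operon > stress.
    """

    keywords: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        unknown = set(self.keywords) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown vocabulary categories: {sorted(unknown)}")

    def categorize(self, product: str) -> str | None:
        """Category of a product annotation, or None if uncategorized."""
        text = product.lower()
        for category in CATEGORIES:
            for kw in self.keywords.get(category, ()):
                if kw.lower() in text:
                    return category
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContextVocabulary":
        keywords: dict[str, list[str]] = {}
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:  # header: category<TAB>keyword
            if not line.strip():
                continue
            category, keyword = line.split("\t")
            keywords.setdefault(category, []).append(keyword)
        return cls(keywords={k: tuple(v) for k, v in keywords.items()})

    @classmethod
    def default(cls) -> "ContextVocabulary":
        ref = resources.files("orpscan") / "data" / "context_vocabulary.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class Neighbor:
    """A gene near the target, at signed gene-rank distance (never 0)."""

    feature: GeneFeature
    rank: int


@dataclass(frozen=True)
class ContextLabel:
    category: str
    supporting_loci: tuple[str, ...] = ()
    ranks: tuple[int, ...] = ()
    co_oriented: bool = False

    def __post_init__(self) -> None:
        if self.category not in LABELS:
            raise ValueError(f"unknown context label {self.category!r}")
        if any(r == 0 for r in self.ranks):
            raise ValueError("supporting ranks must be non-zero")


def neighborhood(
    features: list[GeneFeature], target_locus: str, window_genes: int
) -> list[Neighbor]:
    """Up to ``window_genes`` genes on each side of the target, same contig."""
    target = next((f for f in features if f.locus_id == target_locus), None)
    if target is None:
        raise ValueError(f"target locus {target_locus!r} not found")
    contig = sorted(
        (f for f in features if f.contig == target.contig),
        key=lambda f: (f.start, f.locus_id),
    )
    idx = next(i for i, f in enumerate(contig) if f.locus_id == target_locus)
    out = []
    for i in range(max(0, idx - window_genes), min(len(contig), idx + window_genes + 1)):
        if i != idx:
            out.append(Neighbor(feature=contig[i], rank=i - idx))
    return out


def classify_context(
    neighbors: list[Neighbor],
    vocab: ContextVocabulary | None = None,
    adjacency_rank: int = Thresholds.adjacency_rank,
    proximity_rank: int = Thresholds.proximity_rank,
    taxis_min_neighbors: int = Thresholds.taxis_min_neighbors,
    target_strand: str | None = None,
) -> ContextLabel:
    """Apply the context rules to a neighbor list (see module docstring)."""
    vocab = vocab or ContextVocabulary.default()
    categorized = [
        (nb, vocab.categorize(nb.feature.product))
        for nb in neighbors
        if vocab.categorize(nb.feature.product) is not None
    ]

    def support(category: str, max_rank: int) -> list[Neighbor]:
        return sorted(
            (nb for nb, cat in categorized if cat == category and abs(nb.rank) <= max_rank),
            key=lambda nb: (abs(nb.rank), nb.rank),
        )

    def label(category: str, supp: list[Neighbor]) -> ContextLabel:
        co = bool(supp) and target_strand is not None and all(
            nb.feature.strand == target_strand for nb in supp
        )
        return ContextLabel(
            category=category,
            supporting_loci=tuple(nb.feature.locus_id for nb in supp),
            ranks=tuple(nb.rank for nb in supp),
            co_oriented=co,
        )

    transducers = support("transducer", adjacency_rank)
    if transducers:
        return label("transducer_adjacent", transducers)
    taxis = support("taxis_operon", proximity_rank)
    if len(taxis) >= taxis_min_neighbors:
        return label("taxis_operon_proximal", taxis)
    stress = support("stress", proximity_rank)
    if stress:
        return label("stress_proximal", stress)
    return ContextLabel(category="unlinked")


def classify_locus(
    features: list[GeneFeature],
    target_locus: str,
    vocab: ContextVocabulary | None = None,
    thresholds: Thresholds | None = None,
) -> ContextLabel:
    """Convenience: neighborhood + classification at configured windows."""
    thresholds = thresholds or Thresholds()
    target = next((f for f in features if f.locus_id == target_locus), None)
    if target is None:
        raise ValueError(f"target locus {target_locus!r} not found")
    nbs = neighborhood(features, target_locus, thresholds.proximity_rank)
    return classify_context(
        nbs, vocab,
        adjacency_rank=thresholds.adjacency_rank,
        proximity_rank=thresholds.proximity_rank,
        taxis_min_neighbors=thresholds.taxis_min_neighbors,
        target_strand=target.strand,
    )
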