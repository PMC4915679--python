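"""Distance-based phylogenetics: p/Poisson distances, neighbor joining,
and a monophyly test.

Neighbor joining is the Saitou-Nei agglomeration with two determinism
guarantees: ties in the Q criterion go to the lexicographically smallest
label pair (each internal node is labelled by the smallest leaf beneath
it), and negative branch-length estimates are clamped to zero with the
difference transferred to the sibling edge (logged).  On additive
distances NJ is consistent, so topology and branch lengths are recovered
exactly.

Trees are :class:`dendropy.Tree` objects; Newick serialization and path
lengths come from dendropy.
"""

from __future__ import annotations

import itertools
import logging
import math

import dendropy
import numpy as np
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


def distance_matrix(
    aligned: dict[str, str], correction: str = "p"
) -> DistanceMatrix:
    """Pairwise distances over gapped sequences (pairwise gap deletion).

    ``correction="p"`` gives the raw proportion of differing comparable
    columns; ``"poisson"`` applies -ln(1 - p), erroring on saturation
    (p >= 1).
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = list(aligned)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in aligned.values()}) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = aligned[labels[i]], aligned[labels[j]]
        comparable = diffs = 0
        for x, y in zip(a, b):
            if x == "-" or y == "-":
                continue
            comparable += 1
            diffs += x != y
        if comparable == 0:
            raise ValueError(
                f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
            )
        p = diffs / comparable
        if correction == "poisson":
            if p >= 1.0:
                raise ValueError(f"saturated: p=1 between {labels[i]!r} and {labels[j]!r}")
            d = -math.log(1.0 - p)
        else:
            d = p
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


def _new_tree(taxa: list[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = {}
    for t in taxa:
        node = dendropy.Node(taxon=ns.get_taxon(t))
        nodes[t] = node
    return tree, nodes


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaks."""
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    labels = list(dm.ids)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")

    tree, nodes = _new_tree(labels)
    # working state: list of active cluster labels; label -> dendropy node;
    # internal clusters labelled by their smallest leaf for tie-breaking
    active = list(labels)
    dist = {
        (a, b): d[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }

    def get(a: str, b: str) -> float:
        return dist[(a, b)]

    def attach(parent: dendropy.Node, child_label: str, length: float) -> None:
        child = nodes[child_label]
        parent.add_child(child)
        child.edge.length = length

    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * get(a, b) - r[a] - r[b]
            if best is None or q < best - 1e-12:
                best, best_pair = q, (a, b)
        a, b = best_pair  # type: ignore[misc]
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            logger.warning("clamping negative branch length %.4g on %s", la, a)
            lb += -la
            la = 0.0
        if lb < 0:
            logger.warning("clamping negative branch length %.4g on %s", lb, b)
            la += -lb
            lb = 0.0
        new_label = min(a, b)
        parent = dendropy.Node()
        attach(parent, a, la)
        attach(parent, b, lb)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (get(a, c) + get(b, c) - dab)
            dist[(new_label, c)] = dist[(c, new_label)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)]
        active.append(new_label)
        nodes[new_label] = parent

    if len(active) == 2:
        a, b = sorted(active)
        dab = get(a, b)
        root = dendropy.Node()
        attach(root, a, dab / 2)
        attach(root, b, dab / 2)
    else:
        a, b, c = sorted(active)
        dab, dac, dbc = get(a, b), get(a, c), get(b, c)
        la = max((dab + dac - dbc) / 2, 0.0)
        lb = max((dab + dbc - dac) / 2, 0.0)
        lc = max((dac + dbc - dab) / 2, 0.0)
        root = dendropy.Node()
        attach(root, a, la)
        attach(root, b, lb)
        attach(root, c, lc)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, labelset: set[str] | frozenset[str] | list[str]) -> bool:
    """True iff some edge bipartitions the leaves into ``labelset`` vs rest.

    Singletons and the full leaf set are trivially monophyletic on an
    unrooted tree.
    """
    labelset = set(labelset)
    leaves = leaf_labels(tree)
    unknown = labelset - leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(labelset) in (0, 1, len(leaves)):
        return len(labelset) != 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == labelset or (leaves - below) == labelset:
            return True
    return False


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for t1, t2 in itertools.combinations(taxa, 2):
        key = tuple(sorted((t1.label, t2.label)))
        out[key] = pdm.patristic_distance(t1, t2)
    return out
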