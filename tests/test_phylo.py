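import itertools
import math
import random

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from orpscan.phylo import (
    distance_matrix,
    is_monophyletic,
    neighbor_joining,
    patristic_distances,
    to_newick,
)


def test_p_distance_identical_and_saturated():
    dm = distance_matrix({"a": "MKWLE", "b": "MKWLE"}, correction="p")
    assert dm["a", "b"] == 0.0
    dm = distance_matrix({"a": "AAAAAAAAAA", "b": "WWWWWWWWWW"}, correction="p")
    assert dm["a", "b"] == 1.0
    with pytest.raises(ValueError, match="saturated"):
        distance_matrix({"a": "AAAAAAAAAA", "b": "WWWWWWWWWW"}, correction="poisson")


def test_poisson_correction_closed_form():
    # p = 0.5 -> -ln(0.5)
    dm = distance_matrix({"a": "AAAAAAAAAA", "b": "AAAAAWWWWW"}, correction="poisson")
    assert dm["a", "b"] == pytest.approx(math.log(2), abs=1e-9)


def test_pairwise_deletion_ignores_gapped_columns():
    dm = distance_matrix({"a": "A-AAA", "b": "AW-AA"}, correction="p")
    assert dm["a", "b"] == 0.0  # only 3 comparable columns, all equal


def test_no_comparable_columns_errors():
    with pytest.raises(ValueError, match="comparable"):
        distance_matrix({"a": "A--", "b": "-AA"})


def test_two_taxon_tree_single_edge():
    tree = neighbor_joining(DistanceMatrix([[0, 3], [3, 0]], ids=["A", "B"]))
    assert patristic_distances(tree)[("A", "B")] == pytest.approx(3.0)


def test_three_taxon_closed_form_pendant_lengths():
    dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"])
    tree = neighbor_joining(dm)
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def _random_additive_tree(n: int, seed: int):
    """A random binary tree with uniform branch lengths and its exact
    patristic distance matrix (the oracle NJ must reproduce)."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    leaves = [dendropy.Node(taxon=ns.get_taxon(t)) for t in taxa[:3]]
    for leaf in leaves:
        tree.seed_node.add_child(leaf)
    edges = list(leaves)
    for t in taxa[3:]:
        split_node = edges[rng.integers(len(edges))]
        parent = split_node.parent_node
        inner = dendropy.Node()
        parent.remove_child(split_node)
        parent.add_child(inner)
        inner.add_child(split_node)
        new_leaf = dendropy.Node(taxon=ns.get_taxon(t))
        inner.add_child(new_leaf)
        edges += [inner, new_leaf]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.1, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    tx = list(tree.taxon_namespace)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pdm.patristic_distance(tx[i], tx[j])
    return tree, DistanceMatrix(mat, ids=[t.label for t in tx])


def _bipartitions(tree: dendropy.Tree) -> set:
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            out.add(min(below, leaves - below, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


@pytest.mark.parametrize("seed", range(10))
def test_nj_consistency_on_additive_distances(seed):
    n = 4 + seed % 5
    true_tree, dm = _random_additive_tree(n, seed)
    rec = neighbor_joining(dm)
    assert _bipartitions(rec) == _bipartitions(true_tree)
    pd_rec = patristic_distances(rec)
    for (a, b), d in pd_rec.items():
        assert d == pytest.approx(dm[a, b], abs=1e-9)


def test_nj_topology_agrees_with_skbio():
    _, dm = _random_additive_tree(7, seed=99)
    ours = neighbor_joining(dm)
    import io as _io

    buf = _io.StringIO()
    skbio_nj(dm).write(buf)  # skbio -> newick string
    theirs_newick = buf.getvalue()
    theirs = dendropy.Tree.get(data=theirs_newick, schema="newick")
    assert _bipartitions(ours) == _bipartitions(theirs)


def test_nj_rejects_asymmetric_matrix():
    class FakeDM:
        data = np.array([[0.0, 1.0], [2.0, 0.0]])
        ids = ["a", "b"]

    with pytest.raises(ValueError, match="symmetric"):
        neighbor_joining(FakeDM())


def test_newick_serialization_round_trips():
    _, dm = _random_additive_tree(5, seed=3)
    tree = neighbor_joining(dm)
    back = dendropy.Tree.get(data=to_newick(tree), schema="newick")
    assert _bipartitions(back) == _bipartitions(tree)


def test_monophyly_trivial_and_nontrivial_cases():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
    labels = {"A", "B", "C", "D"}
    assert is_monophyletic(tree, labels)
    assert is_monophyletic(tree, {"A"})
    assert is_monophyletic(tree, {"A", "B"})
    assert not is_monophyletic(tree, {"A", "C"})
    with pytest.raises(ValueError, match="not in tree"):
        is_monophyletic(tree, {"Z"})
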