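"""Tree comparison metrics and the simulation-study scoring.

Robinson-Foulds (RF) distance is the size of the symmetric difference of
the two trees' non-trivial bipartition sets; the weighted variant (wRF)
sums |branch length difference| over the union of bipartitions, with a
bipartition absent from one tree contributing its full length. An estimate
counts as "close" to the truth when its RF distance is at most 4 — the same
topology or within two NNI rearrangements, each of which changes the
bipartition set by at most one split pair.

Random binary trees (uniform over labeled unrooted topologies, by
sequential addition at a uniformly chosen edge) provide the null baseline:
for n tips the maximum RF to any binary tree is 2(n-3), and random trees
sit essentially at that ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

__all__ = [
    "TreeDistanceReport",
    "rf_distance",
    "weighted_rf",
    "is_close",
    "random_binary_tree",
    "random_tree_baseline",
    "score_simulation",
    "compare_trees",
]

CLOSE_RF_DEFAULT = 4


@dataclass
class TreeDistanceReport:
    rf: int
    wrf: float
    close: bool


def _common_namespace(a: dendropy.Tree, b: dendropy.Tree) -> tuple[dendropy.Tree, dendropy.Tree]:
    if a.taxon_namespace is b.taxon_namespace:
        return a, b
    tns = dendropy.TaxonNamespace()
    a2 = a.clone(depth=1)
    b2 = b.clone(depth=1)
    a2.migrate_taxon_namespace(tns)
    b2.migrate_taxon_namespace(tns)
    return a2, b2


def _check_tips(a: dendropy.Tree, b: dendropy.Tree) -> None:
    ta = {leaf.taxon.label for leaf in a.leaf_node_iter()}
    tb = {leaf.taxon.label for leaf in b.leaf_node_iter()}
    if ta != tb:
        raise ValueError(
            f"tip sets differ: only-in-first={sorted(ta - tb)}, "
            f"only-in-second={sorted(tb - ta)}"
        )


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance (symmetric bipartition difference)."""
    a, b = _common_namespace(a, b)
    _check_tips(a, b)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def _fill_missing_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    if any(e.length is None for e in tree.preorder_edge_iter()):
        tree = tree.clone(depth=1)
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 0.0
    return tree


def weighted_rf(a: dendropy.Tree, b: dendropy.Tree) -> float:
    """Weighted RF: sum of |length_a - length_b| over the bipartition union
    (absent bipartitions contribute their full length; missing lengths count
    as zero)."""
    a, b = _common_namespace(a, b)
    _check_tips(a, b)
    a = _fill_missing_lengths(a)
    b = _fill_missing_lengths(b)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return float(treecompare.weighted_robinson_foulds_distance(a, b))


def is_close(a: dendropy.Tree, b: dendropy.Tree, max_rf: int = CLOSE_RF_DEFAULT) -> bool:
    """True when the topologies are identical or within ``max_rf`` RF units
    (default 4 = two NNI rearrangements)."""
    return rf_distance(a, b) <= max_rf


def random_binary_tree(
    labels: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Uniformly random labeled unrooted binary topology by sequential
    addition: taxon i+1 joins one of the 2i-3 current edges chosen uniformly
    (each topology arises from exactly one choice path, so the distribution
    is uniform). Branch lengths are set to 1."""
    if rng is None:
        rng = np.random.default_rng()
    if taxon_namespace is not None:
        taxa = list(taxon_namespace)
    else:
        if labels is None:
            raise ValueError("provide labels or a taxon_namespace")
        taxon_namespace = dendropy.TaxonNamespace(list(labels))
        taxa = list(taxon_namespace)
    if len(taxa) < 3:
        raise ValueError("need at least 3 tips")
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = False
    for taxon in taxa[:3]:
        child = dendropy.Node(taxon=taxon)
        child.edge.length = 1.0
        tree.seed_node.add_child(child)
    edges = [child.edge for child in tree.seed_node.child_nodes()]
    for taxon in taxa[3:]:
        edge = edges[int(rng.integers(0, len(edges)))]
        head, parent = edge.head_node, edge.head_node.parent_node
        mid = dendropy.Node()
        parent.remove_child(head)
        parent.add_child(mid)
        mid.add_child(head)
        mid.edge.length = 1.0
        head.edge.length = 1.0
        tip = dendropy.Node(taxon=taxon)
        tip.edge.length = 1.0
        mid.add_child(tip)
        edges.extend([head.edge, tip.edge, mid.edge])
    return tree


def random_tree_baseline(
    reference: dendropy.Tree,
    n_trees: int,
    rng: np.random.Generator | None = None,
) -> dict:
    """RF distances of *n_trees* uniformly random binary trees to a fixed
    reference; the null distribution against which an inferred tree's RF is
    judged. Returns min / mean / max."""
    if rng is None:
        rng = np.random.default_rng()
    tns = reference.taxon_namespace
    reference.encode_bipartitions()
    dists = np.empty(n_trees)
    for i in range(n_trees):
        tree = random_binary_tree(taxon_namespace=tns, rng=rng)
        dists[i] = treecompare.symmetric_difference(reference, tree)
    return {
        "min": float(dists.min()),
        "mean": float(dists.mean()),
        "max": float(dists.max()),
        "n": n_trees,
    }


def score_simulation(
    estimated: Sequence[dendropy.Tree],
    truth: dendropy.Tree,
    max_rf: int = CLOSE_RF_DEFAULT,
) -> dict:
    """Study scoring: C = fraction of estimates 'close' to the truth,
    wRF = mean weighted RF distance."""
    if not estimated:
        raise ValueError("no estimated trees")
    closes = [is_close(t, truth, max_rf=max_rf) for t in estimated]
    wrfs = [weighted_rf(t, truth) for t in estimated]
    return {
        "C": float(np.mean(closes)),
        "wRF": float(np.mean(wrfs)),
        "n": len(estimated),
    }


def compare_trees(a: dendropy.Tree, b: dendropy.Tree, max_rf: int = CLOSE_RF_DEFAULT) -> TreeDistanceReport:
    rf = rf_distance(a, b)
    return TreeDistanceReport(rf=rf, wrf=weighted_rf(a, b), close=rf <= max_rf)
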