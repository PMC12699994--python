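"""Tree inference from topic frequencies by restricted maximum likelihood
under Brownian motion (a reimplementation of PHYLIP Contml's model).

Model. Each character (a per-locus topic frequency, square-root transformed
by default) evolves independently along the unrooted tree as Brownian
motion: the net change over a branch of length t is N(0, c t), with the rate
constant c fixed at 1 and absorbed into the branch lengths. Because the root
state is unknown, the likelihood is restricted to the n-1 root-independent
contrasts produced by Felsenstein's pruning: merging two subtrees with
profiles x_a, x_b and accumulated variances v_a, v_b yields the contrast
u = x_a - x_b with variance v_a + v_b, the merged profile
(v_b x_a + v_a x_b)/(v_a + v_b), and the extra variance v_a v_b/(v_a + v_b)
passed upward. The restricted log-likelihood over p characters is

    sum_i [ -(p/2) log(2 pi v_i) - ||u_i||^2 / (2 v_i) ]

and is invariant to root placement and tip input order.

Implementation notes. Every node profile is a linear combination of tip
rows, so it is carried as a coefficient vector over tips; squared contrast
norms are quadratic forms in the precomputed Gram matrix X X^T, making each
likelihood evaluation O(n^2) regardless of the character count. Branch
lengths are optimized by exact coordinate ascent: re-rooting the pruning at
a focal edge isolates its length t in a single contrast with variance
(delta_a + delta_b + t), maximized in closed form at
t* = max(0, ||u||^2 / p - delta_a - delta_b). Topology search is stepwise
addition in row order followed by nearest-neighbor-interchange sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import dendropy
import numpy as np

from .topics import TopicFit

__all__ = [
    "FrequencyMatrix",
    "assemble_matrix",
    "sqrt_transform",
    "reml_loglik",
    "optimize_branch_lengths",
    "search_tree",
    "exhaustive_search",
    "enumerate_topologies",
]

_EPS = 1e-8  # floor on contrast variances during evaluation


# -- character matrix ------------------------------------------------------


@dataclass
class FrequencyMatrix:
    """Tips x characters matrix of per-locus topic frequencies.

    In gene-frequency mode each locus contributes M_l - 1 columns (the last
    topic is dropped because frequencies sum to one) and entries are
    square-root transformed, the standard variance-stabilizing choice for
    frequencies drifting under Brownian motion.
    """

    labels: list[str]
    X: np.ndarray
    locus_topics: list[int] = field(default_factory=list)
    transform: Literal["none", "sqrt"] = "none"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValueError("X must be 2-D with one row per label")

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_characters(self) -> int:
        return self.X.shape[1]


def assemble_matrix(
    fits: Sequence[TopicFit],
    group_order: Sequence[str],
    drop_last: bool = True,
    transform: Literal["none", "sqrt"] = "sqrt",
) -> FrequencyMatrix:
    """Concatenate per-locus theta blocks into the tree-inference input.

    Row order follows *group_order*; per locus the last topic column is
    dropped by default (gene-frequency convention), giving
    sum_l (M_l - 1) columns.
    """
    if not fits:
        raise ValueError("no topic fits given")
    labels = list(group_order)
    blocks: list[np.ndarray] = []
    locus_topics: list[int] = []
    for fit in fits:
        row_of = {lab: i for i, lab in enumerate(fit.labels)}
        missing = [lab for lab in labels if lab not in row_of]
        if missing:
            raise ValueError(
                f"locus {fit.locus_id!r} is missing tips {missing}; every "
                f"locus must cover every tip"
            )
        theta = fit.theta[[row_of[lab] for lab in labels], :]
        blocks.append(theta[:, :-1] if drop_last else theta)
        locus_topics.append(fit.num_topics)
    matrix = FrequencyMatrix(
        labels=labels,
        X=np.concatenate(blocks, axis=1),
        locus_topics=locus_topics,
        transform="none",
    )
    if transform == "sqrt":
        matrix = sqrt_transform(matrix)
    return matrix


def sqrt_transform(matrix: FrequencyMatrix) -> FrequencyMatrix:
    """Entrywise square root (variance stabilization for frequencies)."""
    if np.any(matrix.X < 0):
        raise ValueError("sqrt transform requires nonnegative entries")
    if matrix.transform == "sqrt":
        return matrix
    return replace(matrix, X=np.sqrt(matrix.X), transform="sqrt")


# -- internal unrooted tree structure --------------------------------------
#
# adjacency as dict-of-dicts {node: {neighbor: branch_length}}; tips are
# 0..n-1 (row indices of the matrix), internal nodes get ids >= n.


def _edges(adj: dict[int, dict[int, float]]) -> list[tuple[int, int]]:
    return sorted((u, v) for u in adj for v in adj[u] if u < v)


def _add_edge(adj, u, v, length) -> None:
    adj.setdefault(u, {})[v] = length
    adj.setdefault(v, {})[u] = length


def _del_edge(adj, u, v) -> None:
    del adj[u][v]
    del adj[v][u]
    for x in (u, v):
        if not adj[x]:
            del adj[x]


def _prune_side(adj, G, node, parent, contrasts=None):
    """Prune the side of edge (parent, node) rooted at *node*.

    Returns (profile weight vector over tips, accumulated extra variance at
    node). The branch node->parent is NOT included in the variance. If
    *contrasts* is a list, (quadratic form, variance) pairs for every
    contrast inside this side are appended to it.
    """
    children = [x for x in adj[node] if x != parent]
    if not children:
        w = np.zeros(G.shape[0])
        w[node] = 1.0
        return w, 0.0
    w = None
    v = 0.0
    for child in sorted(children):
        cw, cv = _prune_side(adj, G, child, node, contrasts)
        cv = cv + max(adj[node][child], 0.0)
        if w is None:
            w, v = cw, cv
            continue
        V = max(v + cv, _EPS)
        if contrasts is not None:
            d = w - cw
            contrasts.append((float(d @ G @ d), V))
        w = (cv * w + v * cw) / (v + cv) if v + cv > 0 else 0.5 * (w + cw)
        v = v * cv / (v + cv) if v + cv > 0 else 0.0
    return w, v


def _loglik_adj(adj, G, p) -> float:
    """Restricted log-likelihood of the whole tree (rooted on any edge)."""
    (u, v) = _edges(adj)[0]
    contrasts: list[tuple[float, float]] = []
    wa, da = _prune_side(adj, G, u, v, contrasts)
    wb, db = _prune_side(adj, G, v, u, contrasts)
    d = wa - wb
    V = max(da + db + max(adj[u][v], 0.0), _EPS)
    contrasts.append((float(d @ G @ d), V))
    return sum(
        -0.5 * (p * math.log(2.0 * math.pi * V) + q / V) for q, V in contrasts
    )


def _update_edge(adj, G, p, u, v) -> None:
    """Closed-form REML coordinate update of one branch length: re-rooted at
    edge (u, v), the restricted likelihood depends on t only through the
    final contrast's variance delta_a + delta_b + t, maximized at
    ||u||^2 / p."""
    wa, da = _prune_side(adj, G, u, v)
    wb, db = _prune_side(adj, G, v, u)
    d = wa - wb
    q = float(d @ G @ d)
    t = max(0.0, q / p - da - db)
    adj[u][v] = adj[v][u] = t


def _optimize_adj(adj, G, p, tol=1e-6, max_sweeps=1000) -> float:
    last = _loglik_adj(adj, G, p)
    for _ in range(max_sweeps):
        for (u, v) in _edges(adj):
            _update_edge(adj, G, p, u, v)
        cur = _loglik_adj(adj, G, p)
        if cur - last < tol:
            last = cur
            break
        last = cur
    return last


# -- dendropy conversion ---------------------------------------------------


def _adj_to_dendropy(
    adj, labels: Sequence[str], taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    tns = taxon_namespace or dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    n = len(labels)
    root_id = next(x for x in sorted(adj) if x >= n) if any(x >= n for x in adj) else None
    if root_id is None:  # 2-node tree cannot occur (>=3 tips enforced upstream)
        raise ValueError("tree has no internal node")

    def build(node_id, parent_id, parent_dnode):
        if node_id < n:
            dnode = dendropy.Node(taxon=tns.get_taxon(labels[node_id]))
        else:
            dnode = dendropy.Node()
        if parent_dnode is None:
            tree.seed_node = dnode
        else:
            parent_dnode.add_child(dnode)
            dnode.edge.length = adj[node_id][parent_id]
        for nbr in sorted(adj[node_id]):
            if nbr != parent_id:
                build(nbr, node_id, dnode)
        return dnode

    build(root_id, None, None)
    return tree


def _dendropy_to_adj(tree: dendropy.Tree, labels: Sequence[str]):
    row = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    adj: dict[int, dict[int, float]] = {}
    ids: dict[dendropy.Node, int] = {}
    next_id = n
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            lab = node.taxon.label
            if lab not in row:
                raise ValueError(f"tree tip {lab!r} not among matrix rows")
            ids[node] = row[lab]
        else:
            ids[node] = next_id
            next_id += 1
    seen = set()
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            seen.add(node.taxon.label)
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 0.0
            _add_edge(adj, ids[node], ids[node.parent_node], float(length))
    missing = [lab for lab in labels if lab not in seen]
    if missing:
        raise ValueError(f"tree is missing tips {missing}")
    # unroot a degree-2 root by fusing its two incident edges
    root = ids[tree.seed_node]
    if root in adj and len(adj[root]) == 2:
        (a, la), (b, lb) = list(adj[root].items())
        _del_edge(adj, root, a)
        _del_edge(adj, root, b)
        _add_edge(adj, a, b, la + lb)
    return adj


# -- public API ------------------------------------------------------------


def reml_loglik(tree: dendropy.Tree, matrix: FrequencyMatrix) -> float:
    """Restricted log-likelihood of *matrix* on *tree* (branch lengths as
    given, zero-length branches floored at 1e-8 through the variance floor).
    Invariant to root placement and tip input order."""
    if matrix.n_tips < 3:
        raise ValueError("need at least 3 tips")
    adj = _dendropy_to_adj(tree, matrix.labels)
    G = matrix.X @ matrix.X.T
    return _loglik_adj(adj, G, matrix.n_characters)


def optimize_branch_lengths(
    tree: dendropy.Tree,
    matrix: FrequencyMatrix,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> dendropy.Tree:
    """REML branch lengths on a fixed topology by exact per-edge coordinate
    ascent; stops when a full sweep improves the log-likelihood by < tol.
    The result carries the final log-likelihood as ``tree.logL``."""
    if matrix.n_tips < 3:
        raise ValueError("need at least 3 tips")
    adj = _dendropy_to_adj(tree, matrix.labels)
    G = matrix.X @ matrix.X.T
    logL = _optimize_adj(adj, G, matrix.n_characters, tol=tol, max_sweeps=max_sweeps)
    out = _adj_to_dendropy(adj, matrix.labels, tree.taxon_namespace)
    out.logL = logL
    return out


def _insert_tip(adj, edge, tip, next_id, init_len=0.05):
    u, v = edge
    length = adj[u][v]
    mid = next_id
    _del_edge(adj, u, v)
    _add_edge(adj, u, mid, length / 2.0)
    _add_edge(adj, mid, v, length / 2.0)
    _add_edge(adj, mid, tip, init_len)
    return mid


def _remove_tip(adj, tip):
    (mid,) = list(adj[tip])
    _del_edge(adj, tip, mid)
    (a, la), (b, lb) = list(adj[mid].items())
    _del_edge(adj, mid, a)
    _del_edge(adj, mid, b)
    _add_edge(adj, a, b, la + lb)


def _local_optimize(adj, G, p, edges, rounds=3):
    for _ in range(rounds):
        for (u, v) in edges:
            _update_edge(adj, G, p, u, v)


def _nni_neighbors(adj, u, v):
    """The two NNI rearrangements across internal edge (u, v), as swap
    instructions (subtree-of-u, subtree-of-v)."""
    au = sorted(x for x in adj[u] if x != v)
    av = sorted(x for x in adj[v] if x != u)
    return [(au[0], av[0]), (au[0], av[1])]


def _apply_nni(adj, u, v, a, b):
    """Swap subtree a (neighbor of u) with subtree b (neighbor of v)."""
    la, lb = adj[u][a], adj[v][b]
    _del_edge(adj, u, a)
    _del_edge(adj, v, b)
    _add_edge(adj, u, b, lb)
    _add_edge(adj, v, a, la)


def _nni_sweeps(adj, G, p, logL, repeat=True, tol=1e-6, max_moves=200):
    """Greedy NNI hill climbing; after each accepted move the sweep restarts
    over the (now changed) edge set. Candidate and incumbent scores use the
    same partial-optimization settings, so accepted scores strictly increase
    and the climb terminates. ``repeat=False`` stops after the first
    accepted move or one clean pass."""
    n = G.shape[0]
    logL = _optimize_adj(adj, G, p, tol=1e-5, max_sweeps=50)
    moves = 0
    while moves < max_moves:
        improved = False
        for (u, v) in _edges(adj):
            if u < n or v < n:
                continue  # external edge
            for (a, b) in _nni_neighbors(adj, u, v):
                trial = {x: dict(nbrs) for x, nbrs in adj.items()}
                _apply_nni(trial, u, v, a, b)
                cand = _optimize_adj(trial, G, p, tol=1e-5, max_sweeps=50)
                if cand > logL + tol:
                    adj.clear()
                    adj.update(trial)
                    logL = cand
                    improved = True
                    moves += 1
                    break
            if improved:
                break
        if not improved or not repeat:
            break
    return _optimize_adj(adj, G, p)


def search_tree(
    matrix: FrequencyMatrix,
    seed: int | None = None,
    global_rearrangements: bool = True,
    jumble: bool = False,
) -> dendropy.Tree:
    """Stepwise addition of tips in row order (each insertion point scored by
    REML after local branch optimization), then NNI rearrangements. With
    ``global_rearrangements`` NNI sweeps repeat over all internal edges until
    no improvement; otherwise a single sweep is made. ``jumble`` shuffles the
    addition order using *seed*. Deterministic given row order and seed."""
    n = matrix.n_tips
    if n < 3:
        raise ValueError("need at least 3 tips")
    p = matrix.n_characters
    G = matrix.X @ matrix.X.T
    order = list(range(n))
    if jumble:
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(n))
    adj: dict[int, dict[int, float]] = {}
    center = n  # first internal node
    for tip in order[:3]:
        _add_edge(adj, center, tip, 0.05)
    next_id = n + 1
    _optimize_adj(adj, G, p)
    for tip in order[3:]:
        best = None
        for edge in _edges(adj):
            mid = _insert_tip(adj, edge, tip, next_id)
            _local_optimize(
                adj, G, p,
                [(min(mid, x), max(mid, x)) for x in adj[mid]],
            )
            cand = _loglik_adj(adj, G, p)
            if best is None or cand > best[0]:
                best = (cand, edge)
            _remove_tip(adj, tip)
        mid = _insert_tip(adj, best[1], tip, next_id)
        next_id += 1
        _optimize_adj(adj, G, p, tol=1e-5, max_sweeps=50)
    logL = _optimize_adj(adj, G, p)
    logL = _nni_sweeps(adj, G, p, logL, repeat=global_rearrangements)
    tree = _adj_to_dendropy(adj, matrix.labels)
    tree.logL = logL
    return tree


def enumerate_topologies(
    labels: Sequence[str],
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> Iterator[dendropy.Tree]:
    """All distinct unrooted binary topologies on *labels* (3 tips: 1;
    4: 3; 5: 15; 6: 105; ...), as dendropy trees with unit branch lengths.
    Intended for exhaustive-search oracles at desk scale."""
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    tns = taxon_namespace or dendropy.TaxonNamespace(list(labels))

    def grow(adj, next_tip, next_id):
        if next_tip == n:
            yield {x: dict(nbrs) for x, nbrs in adj.items()}
            return
        for edge in _edges(adj):
            _insert_tip(adj, edge, next_tip, next_id, init_len=1.0)
            yield from grow(adj, next_tip + 1, next_id + 1)
            _remove_tip(adj, next_tip)

    base: dict[int, dict[int, float]] = {}
    for tip in range(3):
        _add_edge(base, n, tip, 1.0)
    for adj in grow(base, 3, n + 1):
        yield _adj_to_dendropy(adj, labels, tns)


def exhaustive_search(matrix: FrequencyMatrix) -> dendropy.Tree:
    """Optimize every unrooted topology independently and return the best
    (oracle for search_tree at <= 5-6 tips)."""
    best = None
    for topo in enumerate_topologies(matrix.labels):
        cand = optimize_branch_lengths(topo, matrix)
        if best is None or cand.logL > best.logL:
            best = cand
    return best
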