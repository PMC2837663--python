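"""Matrix representation with parsimony (MRP) encoding and exact small-scale search.

Each internal edge of each source tree becomes one partial binary
character: taxa on one side of the bipartition get 1, the other side 0,
and taxa absent from that source tree get '?'.  Weighted MRP assigns each
character the support value of its edge.  Pendant edges are
parsimony-uninformative and skipped by default.

The module also carries exact parsimony machinery for validation at small
taxon counts: a vectorized Hartigan scorer (exact for arbitrary node
degrees and missing data) and exhaustive enumeration of unrooted binary
topologies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from smidgen.splits import (
    internal_splits,
    internal_splits_with_support,
    leaf_labels,
    splits_to_rooted_newick,
)

MISSING = -1
ENUMERATION_BOUND = 9


@dataclass(frozen=True)
class MRPMatrix:
    """Partial binary character matrix over a taxon universe.

    columns: (n_taxa, n_characters) int8 array with values 0, 1 and
    MISSING (-1).  weights are positive reals, all 1.0 for unweighted MRP.
    provenance records (source-tree index, canonical split) per character.
    """

    taxa: tuple
    columns: np.ndarray
    weights: np.ndarray
    provenance: tuple

    def __post_init__(self):
        if self.columns.shape != (len(self.taxa), len(self.weights)):
            raise ValueError("matrix shape inconsistent with taxa/weights")
        if np.any(self.weights <= 0):
            raise ValueError("character weights must be positive")

    @property
    def n_characters(self) -> int:
        return self.columns.shape[1]

    def column_symbols(self, j: int) -> str:
        return "".join("?" if v == MISSING else str(v) for v in self.columns[:, j])


def _tree_characters(tree, index: int, include_pendant: bool, need_support: bool):
    """Yield (ones_side, support, split) per encoded edge of one source tree."""
    leaves = frozenset(leaf_labels(tree))
    if len(leaves) < 4:
        warnings.warn(
            f"source tree {index} has {len(leaves)} taxa (< 4): contributes no characters",
            stacklevel=3,
        )
        return
    ref = min(leaves)
    supports = internal_splits_with_support(tree)
    splits = sorted(supports, key=lambda s: tuple(sorted(s)))
    if include_pendant:
        pendant = [frozenset([t]) for t in sorted(leaves)]
        splits = splits + [
            (p if ref not in p else frozenset(leaves - p)) for p in pendant
        ]
    for split in splits:
        support = supports.get(split)
        if need_support and support is None:
            raise ValueError(
                f"source tree {index} lacks a support value on split {sorted(split)}"
            )
        # side labeled 1: the side not containing the tree's smallest taxon
        ones = split if ref not in split else leaves - split
        yield frozenset(ones), support, split


def _encode(source_trees, weighted: bool, taxon_universe, include_pendant: bool) -> MRPMatrix:
    source_trees = list(source_trees)
    if not source_trees:
        raise ValueError("need at least one source tree")
    tree_leaves = [frozenset(leaf_labels(t)) for t in source_trees]
    if taxon_universe is None:
        universe = sorted(set().union(*tree_leaves))
    else:
        universe = sorted(taxon_universe)
        extra = set().union(*tree_leaves) - set(universe)
        if extra:
            raise ValueError(f"source-tree taxa outside universe: {sorted(extra)[:3]}")
    row_of = {t: i for i, t in enumerate(universe)}

    cols, weights, provenance = [], [], []
    for idx, (tree, leaves) in enumerate(zip(source_trees, tree_leaves)):
        for ones, support, split in _tree_characters(tree, idx, include_pendant, weighted):
            col = np.full(len(universe), MISSING, dtype=np.int8)
            for t in leaves:
                col[row_of[t]] = 1 if t in ones else 0
            cols.append(col)
            weights.append(support if weighted else 1.0)
            provenance.append((idx, split))

    columns = (
        np.stack(cols, axis=1) if cols else np.empty((len(universe), 0), dtype=np.int8)
    )
    return MRPMatrix(
        taxa=tuple(universe),
        columns=columns,
        weights=np.asarray(weights, dtype=float),
        provenance=tuple(provenance),
    )


def encode_mrp(source_trees, taxon_universe=None, include_pendant: bool = False) -> MRPMatrix:
    """Unweighted MRP coding: one character per internal edge per source tree."""
    return _encode(source_trees, False, taxon_universe, include_pendant)


def encode_wmrp(source_trees, taxon_universe=None, include_pendant: bool = False) -> MRPMatrix:
    """Weighted MRP coding: character weight = edge support (e.g. bootstrap %)."""
    return _encode(source_trees, True, taxon_universe, include_pendant)


# ---------------------------------------------------------------------------
# exact parsimony machinery (validation-scale)


def _postorder_structure(tree, taxa_rows: dict):
    """Flatten a dendropy tree into (leaf_rows, children lists) in postorder.

    leaf entries are matrix row indices (or None for taxa absent from the
    matrix); internal entries list child positions in the postorder array.
    """
    entries = []
    position = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            entries.append(("leaf", taxa_rows.get(node.taxon.label)))
        else:
            entries.append(("internal", [position[c] for c in node.child_nodes()]))
        position[node] = len(entries) - 1
    return entries


def _hartigan_cost(entries, columns: np.ndarray, weights: np.ndarray) -> float:
    """Weighted parsimony length by Hartigan's algorithm, vectorized over columns.

    State sets are 2-bit masks over {0, 1}; '?' leaves carry both states.
    Exact for any node degree, hence also for trees with a trifurcating
    root (unrooted representation).
    """
    n_chars = columns.shape[1]
    masks = np.empty((len(entries), n_chars), dtype=np.int8)
    cost = np.zeros(n_chars, dtype=float)
    for pos, (kind, payload) in enumerate(entries):
        if kind == "leaf":
            if payload is None:
                masks[pos] = 3
            else:
                col = columns[payload]
                masks[pos] = np.where(col == MISSING, 3, col + 1)
        else:
            child = masks[payload]
            votes0 = ((child & 1) > 0).sum(axis=0)
            votes1 = ((child & 2) > 0).sum(axis=0)
            best = np.maximum(votes0, votes1)
            cost += child.shape[0] - best
            masks[pos] = np.where(votes0 == best, 1, 0) | np.where(votes1 == best, 2, 0)
    return float((cost * weights).sum())


def fitch_length(tree, matrix: MRPMatrix) -> float:
    """Weighted parsimony score of ``matrix`` on ``tree``.

    Taxa with a determined state in any character must be leaves of the
    tree; taxa that are '?' throughout a character are free.  Rooting does
    not affect the score.
    """
    tree_taxa = set(leaf_labels(tree))
    determined = {
        t for i, t in enumerate(matrix.taxa) if np.any(matrix.columns[i] != MISSING)
    }
    absent = determined - tree_taxa
    if absent:
        raise ValueError(f"tree is missing taxa with determined states: {sorted(absent)[:3]}")
    taxa_rows = {t: i for i, t in enumerate(matrix.taxa)}
    entries = _postorder_structure(tree, taxa_rows)
    return _hartigan_cost(entries, matrix.columns, matrix.weights)


def _enumerate_topologies(k: int):
    """All unrooted binary topologies on leaves 0..k-1 as edge lists.

    Leaves are 0..k-1; internal nodes k..2k-3.  Built by inserting each
    leaf on every edge of every smaller topology ((2k-5)!! trees).
    """
    base = [(k, 0), (k, 1), (k, 2)]
    trees = [base]
    next_leaf = 3
    next_internal = k + 1
    while next_leaf < k:
        grown = []
        for edges in trees:
            for i in range(len(edges)):
                u, v = edges[i]
                w = next_internal
                new = edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (w, next_leaf)]
                grown.append(new)
        trees = grown
        next_leaf += 1
        next_internal += 1
    return trees


def _edges_to_entries(edges, k: int, taxa_rows_by_leaf):
    """Postorder structure of an edge-list topology rooted at leaf 0's neighbor."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = adj[0][0]
    entries = []

    def visit(node, parent):
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            entries.append(("leaf", taxa_rows_by_leaf[node]))
        else:
            pos = [visit(x, node) for x in kids]
            entries.append(("internal", pos))
        return len(entries) - 1

    visit(root, None)
    return entries


def _edges_to_newick(edges, labels):
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = adj[0][0]

    def render(node, parent):
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            return labels[node]
        return "(" + ",".join(render(x, node) for x in kids) + ")"

    return render(root, None) + ";"


def exhaustive_mp(matrix: MRPMatrix, taxa=None):
    """All minimum-score unrooted binary trees for a matrix, by enumeration.

    Limited to 9 taxa (135,135 topologies).  Returns (best_score, trees)
    with trees as dendropy objects sharing one taxon namespace.
    """
    labels = list(matrix.taxa if taxa is None else taxa)
    k = len(labels)
    if k < 4:
        raise ValueError("need at least 4 taxa for an unrooted search")
    if k > ENUMERATION_BOUND:
        raise ValueError(
            f"{k} taxa exceeds the exhaustive bound of {ENUMERATION_BOUND}; "
            "use an external heuristic search (PAUP*, RAxML) at this scale"
        )
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    determined = {
        t
        for i, t in enumerate(matrix.taxa)
        if np.any(matrix.columns[i] != MISSING)
    }
    missing = determined - set(labels)
    if missing:
        raise ValueError(f"taxa with determined states not in search set: {sorted(missing)[:3]}")
    taxa_rows_by_leaf = {i: row_of.get(labels[i]) for i in range(k)}

    best_score = np.inf
    best_edges = []
    for edges in _enumerate_topologies(k):
        entries = _edges_to_entries(edges, k, taxa_rows_by_leaf)
        score = _hartigan_cost(entries, matrix.columns, matrix.weights)
        if score < best_score - 1e-9:
            best_score = score
            best_edges = [edges]
        elif score <= best_score + 1e-9:
            best_edges.append(edges)

    tns = dendropy.TaxonNamespace()
    trees = [
        dendropy.Tree.get(data=_edges_to_newick(e, labels), schema="newick", taxon_namespace=tns)
        for e in best_edges
    ]
    return float(best_score), trees


# ---------------------------------------------------------------------------
# consensus


def _consensus(trees, min_count) -> dendropy.Tree:
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one input tree")
    leafsets = [frozenset(leaf_labels(t)) for t in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("consensus requires identical leaf sets")
    universe = leafsets[0]
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in internal_splits(t):
            counts[split] = counts.get(split, 0) + 1
    kept = {s for s, c in counts.items() if c >= min_count}
    newick = splits_to_rooted_newick(universe, kept)
    return dendropy.Tree.get(data=newick, schema="newick")


def strict_consensus(trees) -> dendropy.Tree:
    """Tree containing exactly the splits present in every input tree."""
    trees = list(trees)
    return _consensus(trees, len(trees))


def majority_consensus(trees) -> dendropy.Tree:
    """Tree containing exactly the splits present in more than half the inputs."""
    trees = list(trees)
    # strictly more than 50%
    return _consensus(trees, len(trees) // 2 + 1)
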