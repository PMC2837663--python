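"""Bipartition (split) utilities shared by the MRP encoder and the evaluator.

A split is represented canonically as the frozenset of leaf labels on the
side that does NOT contain the lexicographically smallest leaf of the tree.
Only non-trivial splits (both sides with >= 2 leaves) are kept, so the split
set of a tree is exactly its set of internal edges viewed unrooted.
"""

from __future__ import annotations

import numpy as np


def node_label(node) -> str:
    """Stable label of a dendropy node: taxon label for leaves, node label otherwise."""
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def leaf_labels(tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _node_leafsets(tree):
    """Postorder map node -> frozenset of leaf labels below it."""
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc = frozenset()
            for ch in node.child_nodes():
                acc |= sets[ch]
            sets[node] = acc
    return sets


def canonical_split(side: frozenset, universe: frozenset) -> frozenset:
    ref = min(universe)
    return frozenset(universe - side) if ref in side else frozenset(side)


def internal_splits(tree) -> set[frozenset]:
    """Set of canonical non-trivial splits of a (rooted or unrooted) tree."""
    sets = _node_leafsets(tree)
    universe = sets[tree.seed_node]
    n = len(universe)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = sets[node]
        if 2 <= len(side) <= n - 2:
            out.add(canonical_split(side, universe))
    return out


def internal_splits_with_support(tree) -> dict[frozenset, float | None]:
    """Canonical non-trivial splits mapped to edge support values.

    Support is read from internal-node labels (the standard Newick
    convention).  When a rooted binary tree yields the same unrooted split
    from both root-adjacent edges, the available label wins.
    """
    sets = _node_leafsets(tree)
    universe = sets[tree.seed_node]
    n = len(universe)
    out: dict[frozenset, float | None] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = sets[node]
        if not (2 <= len(side) <= n - 2):
            continue
        key = canonical_split(side, universe)
        support = None
        if not node.is_leaf() and node.label not in (None, ""):
            try:
                support = float(node.label)
            except ValueError:
                support = None  # identifier label, not a support value
        if key not in out or out[key] is None:
            out[key] = support
    return out


def splits_to_rooted_newick(universe, splits, edge_lengths=None) -> str:
    """Build a Newick string whose unrooted split set equals ``splits``.

    The splits must be pairwise compatible and each must exclude the
    smallest leaf label (i.e. be canonical).  The tree is written rooted at
    the smallest leaf; the split set of the result, read back, is exactly
    the input set.
    """
    universe = frozenset(universe)
    ref = min(universe)
    clades = sorted(splits, key=len, reverse=True)

    children: dict[frozenset, list] = {frozenset(universe): []}
    order = [frozenset(universe)]
    for clade in clades:
        host = None
        for existing in reversed(order):
            if clade < existing:
                host = existing
                break
        if host is None:
            raise ValueError("split %r incompatible with tree under construction" % (set(clade),))
        children[host].append(clade)
        children[clade] = []
        order.append(clade)
    for leaf in sorted(universe):
        host = frozenset(universe)
        for existing in reversed(order):
            if leaf in existing and len(existing) < len(host):
                host = existing
        children[host].append(leaf)

    def render(item):
        if isinstance(item, str):
            return item
        parts = sorted((render(c) for c in children[item]), key=str)
        return "(" + ",".join(parts) + ")"

    return render(frozenset(universe)) + ";"


def random_binary_tree(labels, rng: np.random.Generator):
    """Uniformly random unrooted binary topology over ``labels`` (as edge dict).

    Returned as a Newick string; used for randomized metric tests and by the
    exhaustive-search machinery.
    """
    import dendropy

    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    order = [labels[i] for i in rng.permutation(len(labels))]
    # sequential random edge insertion yields the uniform distribution
    edges = [("_i0", order[0]), ("_i0", order[1]), ("_i0", order[2])]
    next_internal = 1
    for lab in order[3:]:
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        w = "_i%d" % next_internal
        next_internal += 1
        edges.extend([(u, w), (w, v), (w, lab)])
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def render(node, parent):
        nbrs = [x for x in adj[node] if x != parent]
        if not nbrs:
            return node
        return "(" + ",".join(render(x, node) for x in nbrs) + ")"

    newick = render("_i0", None) + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
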