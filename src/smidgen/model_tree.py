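"""Model-tree generation: ultrametric Yule trees and deviation from the clock.

A model tree is a rooted, fully binary :class:`dendropy.Tree` whose edge
lengths are expected substitutions per site.  Trees are first grown
ultrametric under a Yule pure-birth process with a target height (default
1.0), then made non-clocklike by scaling each edge with a factor that
evolves as a clamped Gaussian random walk from the root toward the tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

DEFAULT_TREE_HEIGHT = 1.0


@dataclass(frozen=True)
class DeviationParams:
    """Parameters of the edge-scaling random walk that breaks ultrametricity.

    The scaling factor starts at ``root_factor`` at the root and, moving
    from a parent branch to each daughter branch, is perturbed by a
    N(0, sigma) increment and clamped into [factor_min, factor_max].
    """

    sigma: float = 0.05
    factor_min: float = 0.05
    factor_max: float = 8.0
    root_factor: float = 1.0

    def __post_init__(self):
        if not (0 < self.factor_min <= self.root_factor <= self.factor_max):
            raise ValueError(
                "need 0 < factor_min <= root_factor <= factor_max, got "
                f"{self.factor_min}, {self.root_factor}, {self.factor_max}"
            )
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_yule_tree(n: int, height: float = DEFAULT_TREE_HEIGHT, seed=None) -> dendropy.Tree:
    """Grow an ultrametric rooted binary tree with ``n`` leaves under a Yule process.

    Lineages split at rate 1 per lineage; a uniformly chosen extant lineage
    splits at each event.  After the n-th lineage appears the process runs
    for one more exponential waiting time, and all node times are rescaled
    so that every root-to-leaf path length equals ``height`` exactly.

    Leaves are labelled ``t001``..; internal nodes ``i0001``.. in preorder.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 taxa, got {n}")
    if height <= 0:
        raise ValueError(f"tree height must be > 0, got {height}")
    rng = as_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    start = {}
    tips = []
    for _ in range(2):
        child = root.new_child()
        start[child] = 0.0
        tips.append(child)

    t = 0.0
    k = 2
    while k < n:
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(len(tips)))
        node = tips[i]
        node.edge.length = t - start[node]
        first, second = node.new_child(), node.new_child()
        start[first] = start[second] = t
        tips[i] = first
        tips.append(second)
        k += 1
    t += rng.exponential(1.0 / n)

    width = max(3, len(str(n)))
    for idx, node in enumerate(tips):
        node.edge.length = t - start[node]
        node.taxon = tns.new_taxon(label=f"t{idx + 1:0{width}d}")

    scale = height / t
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale

    _label_internal_nodes(tree)
    return tree


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        counter += 1
        node.label = f"i{counter:04d}"


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    """True when all root-to-leaf path lengths agree within ``tol``."""
    depths = leaf_depths(tree)
    vals = list(depths.values())
    return max(vals) - min(vals) <= tol


def leaf_depths(tree: dendropy.Tree) -> dict:
    """Root-to-leaf path length per leaf label."""
    depth = {tree.seed_node: 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depth[node]
    return out


def node_depths(tree: dendropy.Tree) -> dict:
    """Root-to-node path length for every node."""
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    return depth


def deviate_from_ultrametricity(
    tree: dendropy.Tree,
    params: DeviationParams | None = None,
    seed=None,
) -> dendropy.Tree:
    """Scale each edge by a factor following a clamped random walk from the root.

    The input must be ultrametric.  The factor on each daughter edge is the
    parent edge's factor plus a N(0, sigma) increment, clamped into
    [factor_min, factor_max]; the walk continues from the clamped value.
    Topology is unchanged; a deep copy is returned.  The realized factor and
    raw increment are attached to each node as ``deviation_factor`` /
    ``deviation_increment`` for diagnostics.
    """
    if params is None:
        params = DeviationParams()
    if not is_ultrametric(tree, tol=1e-6):
        raise ValueError("input tree is not ultrametric")
    rng = as_rng(seed)

    out = tree.clone(depth=1)
    out.seed_node.deviation_factor = params.root_factor
    for node in out.preorder_node_iter():
        if node is out.seed_node:
            continue
        incr = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
        factor = min(
            max(node.parent_node.deviation_factor + incr, params.factor_min),
            params.factor_max,
        )
        node.deviation_factor = factor
        node.deviation_increment = incr
        node.edge.length = node.edge.length * factor
    return out
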