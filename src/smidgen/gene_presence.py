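"""Gene presence/absence on the model tree via a birth/loss decay process.

Each gene occupies a connected set of nodes.  A binary presence site starts
at 0 at the root; on every branch an event fires with probability
1 - exp(-lambda * b_norm), where b_norm is the branch length divided by the
total tree length (so the process is independent of tree height).  The
first firing, scanning away from the root, marks the gene's birth; the same
process continued below the birth node marks losses, each loss pruning the
entire subtree below its branch.  Universal genes are born at the root and
never lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from smidgen.model_tree import as_rng, node_depths
from smidgen.splits import node_label

RATE_CLASSES = ("fast", "medium", "slow")
DEFAULT_RATE_CLASS_COUNTS = {"fast": 25, "medium": 50, "slow": 25}


@dataclass(frozen=True)
class DecayParams:
    """Intensity and conventions of the birth/loss decay process.

    lambda_norm is the event intensity per unit of normalized branch length;
    with branch lengths normalized to sum to 1, a whole-tree pass sees about
    lambda_norm expected events.  loss_lambda_norm defaults to lambda_norm
    (births and losses use the same decay process).  birth_anchor selects
    whether the node at the top ("parent") or bottom ("child") of the firing
    branch becomes the birth node.
    """

    lambda_norm: float = 1.0
    loss_lambda_norm: float | None = None
    birth_anchor: str = "parent"

    def __post_init__(self):
        if self.lambda_norm <= 0:
            raise ValueError(f"lambda_norm must be > 0, got {self.lambda_norm}")
        if self.loss_lambda_norm is not None and self.loss_lambda_norm <= 0:
            raise ValueError("loss_lambda_norm must be > 0 when given")
        if self.birth_anchor not in ("parent", "child"):
            raise ValueError(f"birth_anchor must be 'parent' or 'child', got {self.birth_anchor!r}")

    @property
    def effective_loss_lambda(self) -> float:
        return self.lambda_norm if self.loss_lambda_norm is None else self.loss_lambda_norm


@dataclass(frozen=True)
class GenePresence:
    """A gene's footprint on the model tree.

    present_nodes is a connected node-label set containing birth_node;
    taxa are the leaf labels within it (never empty).
    """

    gene_id: str
    birth_node: str
    loss_nodes: frozenset
    present_nodes: frozenset
    universal: bool
    rate_class: str
    taxa: tuple

    def __post_init__(self):
        if self.rate_class not in RATE_CLASSES:
            raise ValueError(f"unknown rate class {self.rate_class!r}")
        if not self.taxa:
            raise ValueError(f"gene {self.gene_id} has an empty taxon set")


def branch_event_probs(tree, lam: float) -> dict:
    """Per-branch firing probability 1 - exp(-lam * b / total_length)."""
    total = 0.0
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            total += node.edge.length or 0.0
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    probs = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        probs[node] = 1.0 - math.exp(-lam * (node.edge.length or 0.0) / total)
    return probs


def _select_candidate(cands, rng):
    """Earliest (smallest date) candidate; exact ties broken uniformly."""
    best = min(d for d, _ in cands)
    pool = [nd for d, nd in cands if d == best]
    if len(pool) == 1:
        return pool[0]
    return pool[int(rng.integers(len(pool)))]


def sample_edge(tree, params: DecayParams | None = None, seed=None, max_passes: int = 100_000):
    """Select one branch via the recursive decay scan; returns its child node.

    Scanning from the root, each branch leading away from the current node
    is tested; if any fires the scan stops there, otherwise it recurses into
    all children and keeps the earliest reported branch (ties uniform at
    random).  A pass with no event anywhere is repeated.
    """
    if params is None:
        params = DecayParams()
    rng = as_rng(seed)
    probs = branch_event_probs(tree, params.lambda_norm)
    depths = node_depths(tree)
    anchor = params.birth_anchor

    def date_of(child):
        # date of a candidate branch = depth of its anchor node
        return depths[child] if anchor == "child" else depths[child.parent_node]

    def scan(node):
        fired = [c for c in node.child_nodes() if rng.random() < probs[c]]
        if fired:
            cands = [(date_of(c), c) for c in fired]
            return _select_candidate(cands, rng)
        cands = []
        for c in node.child_nodes():
            got = scan(c)
            if got is not None:
                cands.append((date_of(got), got))
        if not cands:
            return None
        return _select_candidate(cands, rng)

    for _ in range(max_passes):
        hit = scan(tree.seed_node)
        if hit is not None:
            return hit
    raise RuntimeError(f"no event fired in {max_passes} whole-tree passes; lambda too small?")


def sample_birth_node(tree, params: DecayParams | None = None, seed=None):
    """Birth node of a gene: anchor node of the branch selected by sample_edge."""
    if params is None:
        params = DecayParams()
    rng = as_rng(seed)
    child = sample_edge(tree, params, rng)
    return child.parent_node if params.birth_anchor == "parent" else child


def sample_losses(
    tree,
    birth_node,
    params: DecayParams | None = None,
    seed=None,
    gene_id: str = "gene",
    rate_class: str = "medium",
    max_resamples: int = 100_000,
) -> GenePresence:
    """Prune the subtree below the birth node with the loss decay process.

    On each branch below a still-present node a loss fires with probability
    1 - exp(-lambda * b_norm); the child node and its whole subtree are then
    excluded.  Draws with no surviving leaf are resampled (a usable gene
    must survive in at least one leaf).
    """
    if params is None:
        params = DecayParams()
    rng = as_rng(seed)
    nodes_in_tree = set(tree.preorder_node_iter())
    if birth_node not in nodes_in_tree:
        raise ValueError("birth_node is not a node of the tree")
    probs = branch_event_probs(tree, params.effective_loss_lambda)

    for _ in range(max_resamples):
        present = []
        losses = []
        stack = [birth_node]
        while stack:
            node = stack.pop()
            present.append(node)
            for c in node.child_nodes():
                if rng.random() < probs[c]:
                    losses.append(c)
                else:
                    stack.append(c)
        taxa = tuple(sorted(node_label(nd) for nd in present if nd.is_leaf()))
        if taxa:
            return GenePresence(
                gene_id=gene_id,
                birth_node=node_label(birth_node),
                loss_nodes=frozenset(node_label(nd) for nd in losses),
                present_nodes=frozenset(node_label(nd) for nd in present),
                universal=False,
                rate_class=rate_class,
                taxa=taxa,
            )
    raise RuntimeError(f"no surviving leaves in {max_resamples} resamples")


def make_universal_gene(tree, gene_id: str, rate_class: str = "slow") -> GenePresence:
    """A gene born at the root and never lost, covering every node.

    Universal genes are slow by default, mirroring the use of slowly
    evolving markers for higher-level scaffolds; the all-scaffold study
    design also uses medium-rate universal genes, hence the override.
    """
    nodes = frozenset(node_label(nd) for nd in tree.preorder_node_iter())
    taxa = tuple(sorted(lf.taxon.label for lf in tree.leaf_node_iter()))
    return GenePresence(
        gene_id=gene_id,
        birth_node=node_label(tree.seed_node),
        loss_nodes=frozenset(),
        present_nodes=nodes,
        universal=True,
        rate_class=rate_class,
        taxa=taxa,
    )


def assign_rate_classes(gene_count: int, proportions: dict | None = None, seed=None) -> list:
    """Randomly ordered list of rate classes with exactly the requested counts.

    Default split for 100 genes: 25 fast, 50 medium, 25 slow.
    """
    if proportions is None:
        proportions = DEFAULT_RATE_CLASS_COUNTS
    unknown = set(proportions) - set(RATE_CLASSES)
    if unknown:
        raise ValueError(f"unknown rate classes: {sorted(unknown)}")
    if sum(proportions.values()) != gene_count:
        raise ValueError(
            f"class counts {proportions} sum to {sum(proportions.values())}, expected {gene_count}"
        )
    rng = as_rng(seed)
    classes = [cls for cls in RATE_CLASSES for _ in range(proportions.get(cls, 0))]
    rng.shuffle(classes)
    return classes


def simulate_nonuniversal_gene(
    tree, gene_id: str, rate_class: str, params: DecayParams | None = None, seed=None
) -> GenePresence:
    """Convenience: draw a birth node, then losses, for one non-universal gene."""
    if params is None:
        params = DecayParams()
    rng = as_rng(seed)
    birth = sample_birth_node(tree, params, rng)
    return sample_losses(tree, birth, params, rng, gene_id=gene_id, rate_class=rate_class)
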