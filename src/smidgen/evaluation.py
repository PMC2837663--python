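"""Topological-error scoring of estimated trees against the model tree.

FN rate: internal edges of the model tree missing from the estimate,
divided by the model tree's internal-edge count (n - 3 for a binary tree
on n taxa).  FP rate: internal edges of the estimate absent from the model
tree, divided by the estimate's internal-edge count.  Their mean is the
average topological error, which equals the normalized Robinson-Foulds
distance when both trees are binary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from smidgen.splits import internal_splits, leaf_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorRates:
    """FN/FP/average topological error for one model-vs-estimate comparison."""

    fn_rate: float
    fp_rate: float
    avg_error: float
    n: int
    model_internal_edges: int
    estimated_internal_edges: int

    def __post_init__(self):
        for v in (self.fn_rate, self.fp_rate, self.avg_error):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"error rates must lie in [0, 1], got {v}")


METRICS = ("fn_rate", "fp_rate", "avg_error")


def restrict_tree(tree, taxa):
    """Induced subtree on ``taxa``: prune other leaves, suppress degree-2 nodes.

    Edge lengths across suppressed nodes are summed.  Needed to score
    source trees, whose taxa are a subset of the model tree's.
    """
    taxa = set(taxa)
    if len(taxa) < 3:
        raise ValueError(f"need at least 3 taxa to induce a tree, got {len(taxa)}")
    have = set(leaf_labels(tree))
    outside = taxa - have
    if outside:
        raise ValueError(f"taxa not in tree: {sorted(outside)[:3]}")
    return tree.extract_tree_with_taxa_labels(labels=taxa)


def compare_trees(model, estimated) -> ErrorRates:
    """FN/FP/average error of ``estimated`` against ``model`` (same leaf set).

    Trees are compared as sets of unrooted non-trivial bipartitions.  A
    binary model tree uses the n - 3 denominator for FN; a star estimate
    (no internal edges) gets FP = 0 by convention.
    """
    model_leaves = frozenset(leaf_labels(model))
    est_leaves = frozenset(leaf_labels(estimated))
    if model_leaves != est_leaves:
        raise ValueError(
            f"leaf sets differ (model has {len(model_leaves)}, estimate {len(est_leaves)}; "
            "restrict_tree first)"
        )
    n = len(model_leaves)
    model_splits = internal_splits(model)
    est_splits = internal_splits(estimated)

    fn_denominator = n - 3
    if len(model_splits) != n - 3:
        logger.warning(
            "model tree is not fully resolved (%d internal edges, binary would have %d); "
            "using its actual edge count",
            len(model_splits), n - 3,
        )
        fn_denominator = len(model_splits)

    fn = len(model_splits - est_splits) / fn_denominator if fn_denominator else 0.0
    if est_splits:
        fp = len(est_splits - model_splits) / len(est_splits)
    else:
        logger.warning("estimated tree is a star (no internal edges); FP defined as 0")
        fp = 0.0
    return ErrorRates(
        fn_rate=fn,
        fp_rate=fp,
        avg_error=(fn + fp) / 2.0,
        n=n,
        model_internal_edges=len(model_splits),
        estimated_internal_edges=len(est_splits),
    )


def summarize_condition(rates) -> dict:
    """Mean and standard error per metric over replicate ErrorRates.

    SE is the sample standard deviation divided by sqrt(replicates); a
    single replicate reports SE = 0 by convention (logged).
    """
    rates = list(rates)
    if not rates:
        raise ValueError("no replicates to summarize")
    r = len(rates)
    if r == 1:
        logger.info("single replicate: reporting SE = 0 by convention")
    out = {}
    for metric in METRICS:
        vals = [getattr(x, metric) for x in rates]
        mean = sum(vals) / r
        if r > 1:
            var = sum((v - mean) ** 2 for v in vals) / (r - 1)
            se = math.sqrt(var) / math.sqrt(r)
        else:
            se = 0.0
        out[metric] = (mean, se)
    return out
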