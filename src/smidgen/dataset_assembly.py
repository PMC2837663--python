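"""Assembly of clade-based datasets, scaffold datasets, and the supermatrix.

Clade-based datasets mimic systematists' dense ingroup studies: a clade is
chosen by the same branch-selection process used for gene births, the three
non-universal genes with best coverage inside the clade are kept, and taxa
are restricted to those possessing all three (no missing cells; datasets
with fewer than ten taxa are discarded).  Scaffold datasets sample taxa
uniformly across the whole tree with probability p (the scaffold factor)
and carry 1, 2 or 4 universal genes.  The supermatrix superimposes all
per-gene alignments on the union of dataset taxa, filling absent cells
with '?'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from smidgen.gene_presence import DecayParams, sample_edge
from smidgen.model_tree import as_rng
from smidgen.splits import node_label

logger = logging.getLogger(__name__)

MISSING_CHAR = "?"
MIN_CLADE_DATASET_TAXA = 10
SCAFFOLD_GENE_CHOICES = (1, 2, 4)


@dataclass(frozen=True)
class CladeDataset:
    """Dense matrix over one clade: 3 non-universal genes, no missing cells."""

    clade_root: str
    taxa: tuple
    genes: tuple
    sequences: tuple  # concatenated gene blocks, aligned with taxa

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def as_dict(self) -> dict:
        return dict(zip(self.taxa, self.sequences))


@dataclass(frozen=True)
class ScaffoldDataset:
    """Matrix over taxa sampled tree-wide with probability p; universal genes only."""

    taxa: tuple
    genes: tuple
    sequences: tuple
    scaffold_factor: float

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def as_dict(self) -> dict:
        return dict(zip(self.taxa, self.sequences))


@dataclass(frozen=True)
class SuperMatrix:
    """Merged alignment over all source datasets; one block per distinct gene."""

    taxa: tuple
    blocks: tuple  # (gene_id, start, end) with end exclusive
    sequences: tuple

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def missing_fraction(self) -> float:
        total = len(self.taxa) * self.width
        filled = sum(len(row) - row.count(MISSING_CHAR) for row in self.sequences)
        return 1.0 - filled / total if total else 0.0

    def as_dict(self) -> dict:
        return dict(zip(self.taxa, self.sequences))


def _clade_leaves(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def select_clades(
    tree,
    count: int,
    size_min: int,
    size_max: int | None = None,
    params: DecayParams | None = None,
    seed=None,
    max_attempts: int = 10_000,
):
    """Pick ``count`` distinct clade roots whose leaf counts meet the bounds.

    Each attempt selects an edge with the gene-birth branch-selection
    process; the child node of that edge is the clade root.  Roots are
    rejection-sampled independently until the size bounds are met; a clade
    root is never reused.
    """
    if count < 1:
        raise ValueError("need at least one clade")
    if params is None:
        params = DecayParams()
    rng = as_rng(seed)
    chosen = []
    chosen_set = set()
    attempts = 0
    while len(chosen) < count:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {count} clades with {size_min} <= size <= "
                f"{size_max if size_max is not None else 'inf'} "
                f"in {max_attempts} attempts (found {len(chosen)})"
            )
        attempts += 1
        root = sample_edge(tree, params, rng)
        if root in chosen_set:
            continue
        size = sum(1 for _ in root.leaf_iter())
        if size < size_min:
            continue
        if size_max is not None and size > size_max:
            continue
        chosen.append(root)
        chosen_set.add(root)
    return chosen


def assemble_clade_dataset(
    clade_root,
    gene_presences,
    alignments: dict,
    seed=None,
    min_taxa: int = MIN_CLADE_DATASET_TAXA,
) -> CladeDataset | None:
    """Build the dense 3-gene matrix for one clade, or None when discarded.

    The three non-universal genes covering the most clade taxa are chosen
    (ties broken uniformly at random); taxa are restricted to those holding
    all three genes.  Datasets retaining fewer than ``min_taxa`` taxa are
    discarded.
    """
    rng = as_rng(seed)
    clade_taxa = _clade_leaves(clade_root)
    candidates = [
        g for g in gene_presences if not g.universal and g.gene_id in alignments
    ]
    if len(candidates) < 3:
        raise ValueError(f"need >= 3 non-universal genes with alignments, have {len(candidates)}")

    coverage = {g.gene_id: len(clade_taxa.intersection(g.taxa)) for g in candidates}
    tiebreak = rng.permutation(len(candidates))
    ranked = sorted(
        range(len(candidates)),
        key=lambda i: (-coverage[candidates[i].gene_id], tiebreak[i]),
    )
    picked = [candidates[i] for i in ranked[:3]]

    kept = clade_taxa
    for g in picked:
        kept = kept.intersection(g.taxa)
    if len(kept) < min_taxa:
        logger.info(
            "clade %s discarded: %d taxa with all 3 genes (< %d)",
            node_label(clade_root), len(kept), min_taxa,
        )
        return None

    taxa = tuple(sorted(kept))
    gene_ids = tuple(sorted(g.gene_id for g in picked))
    rows = []
    for taxon in taxa:
        rows.append("".join(alignments[gid].sequence_for(taxon) for gid in gene_ids))
    return CladeDataset(
        clade_root=node_label(clade_root), taxa=taxa, genes=gene_ids, sequences=tuple(rows)
    )


def sample_scaffold(
    tree,
    p: float,
    universal_genes,
    g: int,
    alignments: dict,
    seed=None,
    max_resamples: int = 10_000,
) -> ScaffoldDataset:
    """Sample each taxon independently with probability p; concatenate g universal genes.

    Draws that sample zero taxa are repeated (and logged).
    """
    if not (0 < p <= 1):
        raise ValueError(f"scaffold factor must be in (0, 1], got {p}")
    if g not in SCAFFOLD_GENE_CHOICES:
        raise ValueError(f"scaffold gene count must be one of {SCAFFOLD_GENE_CHOICES}, got {g}")
    universal = [gn for gn in universal_genes if gn.universal]
    if g > len(universal):
        raise ValueError(f"requested {g} universal genes, only {len(universal)} available")
    rng = as_rng(seed)

    idx = rng.choice(len(universal), size=g, replace=False)
    gene_ids = tuple(sorted(universal[i].gene_id for i in idx))
    all_taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    for _ in range(max_resamples):
        mask = rng.random(len(all_taxa)) < p
        taxa = tuple(t for t, m in zip(all_taxa, mask) if m)
        if taxa:
            break
        logger.info("scaffold draw sampled zero taxa at p=%g; resampling", p)
    else:
        raise RuntimeError("scaffold sampling kept returning empty taxon sets")

    rows = tuple(
        "".join(alignments[gid].sequence_for(taxon) for gid in gene_ids) for taxon in taxa
    )
    return ScaffoldDataset(taxa=taxa, genes=gene_ids, sequences=rows, scaffold_factor=p)


def make_all_scaffold_replicate(
    tree,
    universal_genes,
    alignments: dict,
    p: float,
    n_source_trees: int = 6,
    genes_per_source: int = 4,
    seed=None,
):
    """Scaffold-only study design: several scaffold datasets from a universal-gene pool.

    Genes may recur across datasets but are distinct within each one.
    """
    pool = [g for g in universal_genes if g.universal]
    if genes_per_source > len(pool):
        raise ValueError(
            f"genes_per_source={genes_per_source} exceeds universal pool of {len(pool)}"
        )
    rng = as_rng(seed)
    return [
        sample_scaffold(tree, p, pool, genes_per_source, alignments, rng)
        for _ in range(n_source_trees)
    ]


def _dataset_gene_taxa(datasets) -> dict:
    """Per distinct gene, the union of taxa over the datasets that use it."""
    merged: dict[str, set] = {}
    for ds in datasets:
        for gid in ds.genes:
            merged.setdefault(gid, set()).update(ds.taxa)
    return merged


def build_supermatrix(datasets, alignments: dict, universal_ids=None) -> SuperMatrix:
    """Superimpose all dataset alignments into one matrix with '?' for absences.

    One column block per distinct gene; a cell is filled iff its taxon
    belongs to some dataset using that gene.  Blocks are ordered universal
    genes first, then non-universal, by gene id.  Dataset rows are checked
    against the per-gene alignments; a mismatch raises (guards user input).
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one source dataset")
    if universal_ids is None:
        universal_ids = set()
        for ds in datasets:
            if isinstance(ds, ScaffoldDataset):
                universal_ids.update(ds.genes)
    universal_ids = set(universal_ids)

    _check_dataset_consistency(datasets, alignments)

    merged = _dataset_gene_taxa(datasets)
    gene_order = sorted(merged, key=lambda gid: (gid not in universal_ids, gid))
    taxa = tuple(sorted(set().union(*(ds.taxa for ds in datasets))))

    blocks = []
    start = 0
    columns: dict[str, dict] = {}
    for gid in gene_order:
        aln = alignments[gid]
        glen = aln.length
        blocks.append((gid, start, start + glen))
        start += glen
        cover = merged[gid]
        columns[gid] = {
            taxon: (aln.sequence_for(taxon) if taxon in cover else MISSING_CHAR * glen)
            for taxon in taxa
        }

    rows = tuple("".join(columns[gid][taxon] for gid in gene_order) for taxon in taxa)
    return SuperMatrix(taxa=taxa, blocks=tuple(blocks), sequences=rows)


def _check_dataset_consistency(datasets, alignments) -> None:
    for ds in datasets:
        offset = 0
        for gid in ds.genes:
            if gid not in alignments:
                raise ValueError(f"no alignment for gene {gid}")
            aln = alignments[gid]
            glen = aln.length
            for taxon, row in zip(ds.taxa, ds.sequences):
                block = row[offset : offset + glen]
                if block != aln.sequence_for(taxon):
                    raise ValueError(
                        f"conflicting sequence for gene {gid}, taxon {taxon}"
                    )
            offset += glen


def check_dataset_overlap(datasets, min_shared_taxa: int = 3, min_coverage: float = 0.95):
    """Heuristic usability check for super-methods on a set of source datasets.

    Builds a graph with an edge between two datasets sharing at least
    ``min_shared_taxa`` taxa; the set passes when the graph is connected and
    the largest connected component spans at least ``min_coverage`` of all
    sampled taxa.  Returns (ok, details).
    """
    datasets = list(datasets)
    k = len(datasets)
    if k == 0:
        raise ValueError("no datasets")
    taxa_sets = [set(ds.taxa) for ds in datasets]
    adjacency = {i: [] for i in range(k)}
    for i in range(k):
        for j in range(i + 1, k):
            if len(taxa_sets[i] & taxa_sets[j]) >= min_shared_taxa:
                adjacency[i].append(j)
                adjacency[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    connected = len(seen) == k
    union_all = set().union(*taxa_sets)
    component_taxa = set().union(*(taxa_sets[i] for i in seen))
    coverage = len(component_taxa) / len(union_all) if union_all else 0.0
    ok = connected and coverage >= min_coverage
    details = {"connected": connected, "component_coverage": coverage}
    if not ok:
        logger.warning("low taxon overlap among source datasets: %s", details)
    return ok, details
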