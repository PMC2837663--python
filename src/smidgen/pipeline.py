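"""End-to-end replicate orchestration under one seeded configuration.

A replicate runs model-tree generation, gene birth/loss, sequence
evolution, and dataset assembly (clade + scaffold, or the all-scaffold
variant), producing a bundle of in-memory artifacts and, optionally, a
directory of analysis-ready files for external tree estimators.  Every
stage draws its randomness from a seed derived deterministically from the
master seed, the stage name, and the replicate index, so bundles are
bit-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from smidgen import gene_presence, io
from smidgen.dataset_assembly import (
    CladeDataset,
    ScaffoldDataset,
    SuperMatrix,
    assemble_clade_dataset,
    build_supermatrix,
    check_dataset_overlap,
    make_all_scaffold_replicate,
    sample_scaffold,
    select_clades,
)
from smidgen.gene_presence import DecayParams
from smidgen.model_tree import DeviationParams, deviate_from_ultrametricity, generate_yule_tree
from smidgen.seq_evolution import DEFAULT_MODEL_POOL, draw_gene_model, simulate_alignment

logger = logging.getLogger(__name__)

PRESETS = {
    100: dict(clade_count=5, clade_size_min=20, clade_size_max=None, replicates=30),
    500: dict(clade_count=15, clade_size_min=30, clade_size_max=None, replicates=30),
    1000: dict(clade_count=25, clade_size_min=30, clade_size_max=500, replicates=10),
}


@dataclass
class RunConfig:
    """One model condition: tree size, gene counts, scaffold settings, seeds."""

    n: int = 100
    replicates: int = 30
    height: float = 1.0
    deviation: DeviationParams = field(default_factory=DeviationParams)
    decay: DecayParams = field(default_factory=DecayParams)
    universal_genes: int = 5
    nonuniversal_genes: int = 100
    rate_class_counts: dict = field(
        default_factory=lambda: dict(gene_presence.DEFAULT_RATE_CLASS_COUNTS)
    )
    gene_length: int = 500
    clade_count: int = 5
    clade_size_min: int = 20
    clade_size_max: int | None = None
    scaffold_factor: float = 1.0
    scaffold_gene_count: int = 1
    master_seed: int = 0
    mode: str = "standard"  # standard | all_scaffold
    # all-scaffold variant settings
    all_scaffold_pool: dict = field(default_factory=lambda: {"slow": 50, "medium": 50})
    all_scaffold_source_trees: int = 6
    all_scaffold_genes_per_source: int = 4

    def __post_init__(self):
        if self.mode not in ("standard", "all_scaffold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("n", "replicates", "universal_genes", "nonuniversal_genes", "gene_length",
                     "clade_count", "clade_size_min"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_preset(cls, n: int, **overrides) -> "RunConfig":
        if n not in PRESETS:
            raise ValueError(f"no preset for n={n}; presets exist for {sorted(PRESETS)}")
        kwargs = dict(n=n, **PRESETS[n])
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("deviation"), dict):
            d["deviation"] = DeviationParams(**d["deviation"])
        if isinstance(d.get("decay"), dict):
            d["decay"] = DecayParams(**d["decay"])
        return cls(**d)


@dataclass
class ReplicateBundle:
    """All artifacts of one replicate, plus a structured provenance log."""

    config: RunConfig
    replicate_index: int
    model_tree: dendropy.Tree  # the (deviated) true tree
    ultrametric_tree: dendropy.Tree
    genes: list
    alignments: dict
    clade_datasets: list
    scaffold_datasets: list
    supermatrix: SuperMatrix
    log: list
    source_trees: list | None = None
    mrp_matrix: object | None = None
    scores: dict | None = None

    @property
    def datasets(self) -> list:
        return list(self.clade_datasets) + list(self.scaffold_datasets)


def derive_stage_seed(master_seed: int, stage_name: str, replicate_index: int) -> int:
    """Collision-resistant deterministic per-stage seed (< 2^31)."""
    payload = f"{master_seed}|{stage_name}|{replicate_index}".encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stage_rng(config: RunConfig, stage: str, rep: int) -> np.random.Generator:
    return np.random.default_rng(derive_stage_seed(config.master_seed, stage, rep))


def _simulate_genes(config: RunConfig, tree, rep: int, log: list):
    rng = _stage_rng(config, "genes", rep)
    genes = []
    if config.mode == "standard":
        for i in range(config.universal_genes):
            genes.append(gene_presence.make_universal_gene(tree, f"u{i + 1:02d}"))
        classes = gene_presence.assign_rate_classes(
            config.nonuniversal_genes, config.rate_class_counts, rng
        )
        for i, cls in enumerate(classes):
            genes.append(
                gene_presence.simulate_nonuniversal_gene(
                    tree, f"g{i + 1:03d}", cls, config.decay, rng
                )
            )
    else:
        pool_classes = [
            cls for cls in ("slow", "medium", "fast")
            for _ in range(config.all_scaffold_pool.get(cls, 0))
        ]
        rng.shuffle(pool_classes)
        for i, cls in enumerate(pool_classes):
            genes.append(gene_presence.make_universal_gene(tree, f"u{i + 1:03d}", rate_class=cls))
    log.append({"stage": "genes", "count": len(genes)})
    return genes


def _simulate_alignments(config: RunConfig, tree, genes, rep: int, log: list) -> dict:
    rng = _stage_rng(config, "sequences", rep)
    alignments = {}
    skipped = []
    for g in genes:
        model = draw_gene_model(DEFAULT_MODEL_POOL, rng)
        if len(g.taxa) < 2:
            skipped.append(g.gene_id)
            continue
        alignments[g.gene_id] = simulate_alignment(
            g, tree, model, length=config.gene_length, seed=rng
        )
    if skipped:
        logger.info("replicate %d: %d single-leaf genes not simulated: %s",
                    rep, len(skipped), skipped[:5])
    log.append({"stage": "sequences", "simulated": len(alignments), "skipped": skipped})
    return alignments


def run_replicate(config: RunConfig, replicate_index: int, out_dir=None) -> ReplicateBundle:
    """Execute one full replicate; optionally write analysis-ready files.

    Deterministic given (config, replicate_index): every stage reseeds from
    the master seed, the stage name, and the replicate index.
    """
    log: list[dict] = []

    tree_rng = _stage_rng(config, "yule", replicate_index)
    ultrametric = generate_yule_tree(config.n, config.height, tree_rng)
    model_tree = deviate_from_ultrametricity(
        ultrametric, config.deviation, _stage_rng(config, "deviate", replicate_index)
    )
    log.append({"stage": "trees", "n": config.n, "height": config.height})

    genes = _simulate_genes(config, model_tree, replicate_index, log)
    alignments = _simulate_alignments(config, model_tree, genes, replicate_index, log)

    clade_datasets: list[CladeDataset] = []
    scaffold_datasets: list[ScaffoldDataset] = []
    if config.mode == "standard":
        clade_rng = _stage_rng(config, "clades", replicate_index)
        roots = select_clades(
            model_tree,
            config.clade_count,
            config.clade_size_min,
            config.clade_size_max,
            config.decay,
            clade_rng,
        )
        discarded = 0
        for root in roots:
            ds = assemble_clade_dataset(root, genes, alignments, clade_rng)
            if ds is None:
                discarded += 1
            else:
                clade_datasets.append(ds)
        log.append({"stage": "clades", "attempted": len(roots), "discarded": discarded})

        scaffold_rng = _stage_rng(config, "scaffold", replicate_index)
        universal = [g for g in genes if g.universal]
        scaffold_datasets.append(
            sample_scaffold(
                model_tree,
                config.scaffold_factor,
                universal,
                config.scaffold_gene_count,
                alignments,
                scaffold_rng,
            )
        )
        log.append({"stage": "scaffold", "p": config.scaffold_factor,
                    "genes": config.scaffold_gene_count})
    else:
        scaffold_rng = _stage_rng(config, "all_scaffold", replicate_index)
        scaffold_datasets = make_all_scaffold_replicate(
            model_tree,
            genes,
            alignments,
            config.scaffold_factor,
            config.all_scaffold_source_trees,
            config.all_scaffold_genes_per_source,
            scaffold_rng,
        )
        log.append({"stage": "all_scaffold", "p": config.scaffold_factor,
                    "source_trees": len(scaffold_datasets)})

    datasets = clade_datasets + scaffold_datasets
    supermatrix = build_supermatrix(datasets, alignments)
    ok, overlap = check_dataset_overlap(datasets)
    log.append({"stage": "supermatrix", "width": supermatrix.width,
                "missing_fraction": supermatrix.missing_fraction,
                "overlap_ok": ok, **overlap})

    bundle = ReplicateBundle(
        config=config,
        replicate_index=replicate_index,
        model_tree=model_tree,
        ultrametric_tree=ultrametric,
        genes=genes,
        alignments=alignments,
        clade_datasets=clade_datasets,
        scaffold_datasets=scaffold_datasets,
        supermatrix=supermatrix,
        log=log,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ReplicateBundle, out_dir) -> None:
    """Write all replicate artifacts as plain-text analysis-ready files."""
    root = io.ensure_dir(out_dir)
    io.write_newick(bundle.model_tree, root / "model_tree.nwk")
    io.write_newick(bundle.ultrametric_tree, root / "model_tree_ultrametric.nwk")
    io.write_gene_manifest(bundle.genes, root / "genes.tsv")

    gene_dir = io.ensure_dir(root / "genes")
    for gid, aln in bundle.alignments.items():
        io.write_fasta(aln.as_dict(), gene_dir / f"{gid}.fasta")

    ds_dir = io.ensure_dir(root / "datasets")
    for i, ds in enumerate(bundle.clade_datasets):
        io.write_phylip(ds.as_dict(), ds_dir / f"clade_{i + 1:02d}.phy")
    for i, ds in enumerate(bundle.scaffold_datasets):
        io.write_phylip(ds.as_dict(), ds_dir / f"scaffold_{i + 1:02d}.phy")

    io.write_phylip(bundle.supermatrix.as_dict(), root / "supermatrix.phy")
    charsets = [(gid, start, end) for gid, start, end in bundle.supermatrix.blocks]
    io.write_nexus(bundle.supermatrix.as_dict(), root / "supermatrix.nex", charsets=charsets)
    io.write_partitions(bundle.supermatrix.blocks, root / "supermatrix.partitions")

    with open(root / "run_log.json", "w") as fh:
        json.dump(
            {
                "replicate_index": bundle.replicate_index,
                "config": bundle.config.to_dict(),
                "log": bundle.log,
            },
            fh,
            indent=2,
            default=str,
        )


# ---------------------------------------------------------------------------
# toy estimation (smoke-test stand-in for external tree-search tools)


def jc_distance_matrix(rows: dict) -> tuple:
    """Pairwise Jukes-Cantor distances over shared non-missing columns."""
    taxa = list(rows)
    k = len(taxa)
    arr = np.frombuffer("".join(rows[t] for t in taxa).encode(), dtype=np.uint8).reshape(k, -1)
    known = arr != ord("?")
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            shared = known[i] & known[j]
            m = int(shared.sum())
            if m == 0:
                p = 0.74
            else:
                p = float((arr[i, shared] != arr[j, shared]).mean())
            p = min(p, 0.74)  # JC saturation guard
            d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = d
    return taxa, dist


def toy_estimate_tree(dataset) -> dendropy.Tree:
    """Neighbor-joining on JC distances; a placeholder for RAxML/PAUP* runs.

    Intended only for smoke tests of the end-to-end file and scoring
    contracts, not as a serious estimator.
    """
    taxa, dist = jc_distance_matrix(dataset.as_dict())
    import io as _io

    buf = _io.StringIO()
    buf.write("," + ",".join(taxa) + "\n")
    for i, t in enumerate(taxa):
        buf.write(t + "," + ",".join(f"{x:.8f}" for x in dist[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()
    return tree
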