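import math

import numpy as np
import pytest

from smidgen.dataset_assembly import (
    ScaffoldDataset,
    assemble_clade_dataset,
    build_supermatrix,
    check_dataset_overlap,
    make_all_scaffold_replicate,
    sample_scaffold,
    select_clades,
)
from smidgen.gene_presence import DecayParams, GenePresence, make_universal_gene
from smidgen.model_tree import generate_yule_tree
from smidgen.seq_evolution import RBCL, GeneAlignment


def _toy_alignment(gene_id, taxa, length=20, seed=0):
    """Deterministic distinct-sequence stand-in alignment (synthetic)."""
    rng = np.random.default_rng(seed)
    seqs = tuple(
        "".join("ACGT"[c] for c in rng.integers(4, size=length)) for _ in taxa
    )
    return GeneAlignment(
        gene_id=gene_id, taxa=tuple(taxa), sequences=seqs,
        model=RBCL, rate_multiplier=1.0, site_rates=np.ones(length),
    )


def _presence(gene_id, taxa, universal=False, rate_class="medium"):
    return GenePresence(
        gene_id=gene_id, birth_node="i0001", loss_nodes=frozenset(),
        present_nodes=frozenset(taxa) | {"i0001"}, universal=universal,
        rate_class=rate_class, taxa=tuple(sorted(taxa)),
    )


class TestCladeSelection:
    def test_distinct_roots_meeting_bounds(self):
        tree = generate_yule_tree(100, 1.0, seed=31)
        roots = select_clades(tree, 5, 20, seed=1)
        assert len(set(roots)) == 5
        for r in roots:
            assert sum(1 for _ in r.leaf_iter()) >= 20

    def test_upper_bound_respected(self):
        tree = generate_yule_tree(200, 1.0, seed=32)
        roots = select_clades(tree, 8, 10, 60, seed=2)
        for r in roots:
            assert 10 <= sum(1 for _ in r.leaf_iter()) <= 60

    def test_infeasible_bounds_fail_loudly(self):
        tree = generate_yule_tree(10, 1.0, seed=33)
        with pytest.raises(RuntimeError, match="attempts"):
            select_clades(tree, 3, 50, seed=3, max_attempts=200)


class TestCladeDataset:
    def _clade_fixture(self):
        tree = generate_yule_tree(40, 1.0, seed=35)
        # pick the larger root child as a "clade"
        root = max(tree.seed_node.child_nodes(), key=lambda c: len(c.leaf_nodes()))
        clade_taxa = sorted(lf.taxon.label for lf in root.leaf_iter())
        return tree, root, clade_taxa

    def test_intersection_and_no_missing_cells(self):
        tree, root, clade_taxa = self._clade_fixture()
        assert len(clade_taxa) >= 15
        full = clade_taxa
        partial_a = clade_taxa[:-3]          # misses 3
        partial_b = clade_taxa[2:]           # misses 2
        expected = sorted(set(full) & set(partial_a) & set(partial_b))

        genes = [
            _presence("g001", full),
            _presence("g002", partial_a),
            _presence("g003", partial_b),
            _presence("g004", clade_taxa[:4]),  # low coverage, not picked
        ]
        alignments = {
            g.gene_id: _toy_alignment(g.gene_id, g.taxa, seed=i)
            for i, g in enumerate(genes)
        }
        ds = assemble_clade_dataset(root, genes, alignments, seed=0)
        assert ds is not None
        assert ds.genes == ("g001", "g002", "g003")
        assert list(ds.taxa) == expected
        assert ds.width == 3 * 20
        assert "?" not in "".join(ds.sequences)

    def test_small_intersection_discarded(self):
        tree, root, clade_taxa = self._clade_fixture()
        genes = [
            _presence("g001", clade_taxa),
            _presence("g002", clade_taxa[:9]),
            _presence("g003", clade_taxa[:9]),
        ]
        alignments = {
            g.gene_id: _toy_alignment(g.gene_id, g.taxa) for g in genes
        }
        assert assemble_clade_dataset(root, genes, alignments, seed=0) is None

    def test_universal_like_coverage_keeps_all_clade_taxa(self):
        tree, root, clade_taxa = self._clade_fixture()
        genes = [_presence(f"g{i:03d}", clade_taxa) for i in range(1, 4)]
        alignments = {g.gene_id: _toy_alignment(g.gene_id, g.taxa) for g in genes}
        ds = assemble_clade_dataset(root, genes, alignments, seed=0)
        assert list(ds.taxa) == clade_taxa

    def test_needs_three_nonuniversal_genes(self):
        tree, root, clade_taxa = self._clade_fixture()
        genes = [_presence("g001", clade_taxa), _presence("g002", clade_taxa)]
        alignments = {g.gene_id: _toy_alignment(g.gene_id, g.taxa) for g in genes}
        with pytest.raises(ValueError, match="non-universal"):
            assemble_clade_dataset(root, genes, alignments, seed=0)


class TestScaffold:
    def _setup(self, n=30):
        tree = generate_yule_tree(n, 1.0, seed=40)
        genes = [make_universal_gene(tree, f"u{i:02d}") for i in range(1, 6)]
        alignments = {
            g.gene_id: _toy_alignment(g.gene_id, g.taxa, seed=i)
            for i, g in enumerate(genes)
        }
        return tree, genes, alignments

    def test_full_factor_keeps_everyone(self):
        tree, genes, alignments = self._setup()
        ds = sample_scaffold(tree, 1.0, genes, 2, alignments, seed=0)
        assert len(ds.taxa) == 30
        assert ds.width == 2 * 20

    def test_four_genes_width(self):
        tree, genes, alignments = self._setup()
        ds = sample_scaffold(tree, 0.5, genes, 4, alignments, seed=1)
        assert ds.width == 4 * 20
        assert len(set(ds.genes)) == 4

    def test_mean_size_binomial(self):
        tree, genes, alignments = self._setup(n=100)
        rng = np.random.default_rng(5)
        sizes = [
            len(sample_scaffold(tree, 0.2, genes, 1, alignments, rng).taxa)
            for _ in range(2000)
        ]
        se = math.sqrt(100 * 0.2 * 0.8 / len(sizes))
        assert abs(np.mean(sizes) - 20) < 3 * se

    def test_invalid_parameters(self):
        tree, genes, alignments = self._setup()
        with pytest.raises(ValueError):
            sample_scaffold(tree, 0.0, genes, 1, alignments, seed=0)
        with pytest.raises(ValueError):
            sample_scaffold(tree, 0.5, genes, 3, alignments, seed=0)


class TestSupermatrix:
    def test_merge_union_and_missing_pattern(self):
        taxa_a = [f"t{i:02d}" for i in range(10)]
        taxa_b = [f"t{i:02d}" for i in range(5, 15)]
        shared_gene_taxa = sorted(set(taxa_a) | set(taxa_b))
        aln_shared = _toy_alignment("g001", shared_gene_taxa, seed=1)
        aln_a2 = _toy_alignment("g002", taxa_a, seed=2)
        aln_a3 = _toy_alignment("g003", taxa_a, seed=3)
        aln_b2 = _toy_alignment("g004", taxa_b, seed=4)
        aln_b3 = _toy_alignment("g005", taxa_b, seed=5)

        def rows(taxa, alns):
            return tuple("".join(a.sequence_for(t) for a in alns) for t in taxa)

        from smidgen.dataset_assembly import CladeDataset

        ds_a = CladeDataset(
            clade_root="x", taxa=tuple(taxa_a), genes=("g001", "g002", "g003"),
            sequences=rows(taxa_a, [aln_shared, aln_a2, aln_a3]),
        )
        ds_b = CladeDataset(
            clade_root="y", taxa=tuple(taxa_b), genes=("g001", "g004", "g005"),
            sequences=rows(taxa_b, [aln_shared, aln_b2, aln_b3]),
        )
        alignments = {a.gene_id: a for a in (aln_shared, aln_a2, aln_a3, aln_b2, aln_b3)}
        sm = build_supermatrix([ds_a, ds_b], alignments)

        assert sm.taxa == tuple(sorted(set(taxa_a) | set(taxa_b)))
        assert sm.width == 5 * 20
        assert [b[0] for b in sm.blocks] == ["g001", "g002", "g003", "g004", "g005"]
        d = sm.as_dict()
        # shared gene block is filled for the union, others only where used
        g1_start, g1_end = sm.blocks[0][1], sm.blocks[0][2]
        for t in sm.taxa:
            assert "?" not in d[t][g1_start:g1_end]
        g4 = sm.blocks[3]
        assert d["t00"][g4[1]:g4[2]] == "?" * 20  # t00 not in dataset B

        # missing fraction equals a brute-force cell count
        brute = sum(row.count("?") for row in sm.sequences) / (len(sm.taxa) * sm.width)
        assert sm.missing_fraction == pytest.approx(brute)

    def test_conflicting_rows_raise(self):
        taxa = [f"t{i}" for i in range(12)]
        alns = {f"g00{k}": _toy_alignment(f"g00{k}", taxa, seed=k) for k in (1, 2, 3)}
        from smidgen.dataset_assembly import CladeDataset

        rows = tuple(
            "".join(alns[g].sequence_for(t) for g in ("g001", "g002", "g003"))
            for t in taxa
        )
        corrupted = ("A" * 60,) + rows[1:]
        ds = CladeDataset(clade_root="x", taxa=tuple(taxa),
                          genes=("g001", "g002", "g003"), sequences=corrupted)
        with pytest.raises(ValueError, match="conflict"):
            build_supermatrix([ds], alns)


class TestAllScaffold:
    def test_six_sources_of_four_distinct_genes(self):
        tree = generate_yule_tree(25, 1.0, seed=50)
        pool = [
            make_universal_gene(tree, f"u{i:03d}", rate_class=("slow" if i <= 50 else "medium"))
            for i in range(1, 101)
        ]
        alignments = {
            g.gene_id: _toy_alignment(g.gene_id, g.taxa, seed=i)
            for i, g in enumerate(pool)
        }
        datasets = make_all_scaffold_replicate(tree, pool, alignments, p=0.75, seed=6)
        assert len(datasets) == 6
        for ds in datasets:
            assert isinstance(ds, ScaffoldDataset)
            assert len(set(ds.genes)) == 4

    def test_pool_exhaustion_raises(self):
        tree = generate_yule_tree(10, 1.0, seed=51)
        pool = [make_universal_gene(tree, "u001")]
        alignments = {"u001": _toy_alignment("u001", pool[0].taxa)}
        with pytest.raises(ValueError, match="pool"):
            make_all_scaffold_replicate(tree, pool, alignments, p=0.5,
                                        genes_per_source=4, seed=0)


class TestOverlapCheck:
    def test_connected_dense_passes(self):
        taxa = [f"t{i}" for i in range(20)]
        a = ScaffoldDataset(taxa=tuple(taxa[:12]), genes=("u01",),
                            sequences=("A",) * 12, scaffold_factor=0.5)
        b = ScaffoldDataset(taxa=tuple(taxa[8:]), genes=("u01",),
                            sequences=("A",) * 12, scaffold_factor=0.5)
        ok, details = check_dataset_overlap([a, b])
        assert ok and details["connected"]

    def test_disjoint_fails(self):
        a = ScaffoldDataset(taxa=("t1", "t2", "t3"), genes=("u01",),
                            sequences=("A",) * 3, scaffold_factor=0.2)
        b = ScaffoldDataset(taxa=("t8", "t9"), genes=("u01",),
                            sequences=("A",) * 2, scaffold_factor=0.2)
        ok, details = check_dataset_overlap([a, b])
        assert not ok and not details["connected"]
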