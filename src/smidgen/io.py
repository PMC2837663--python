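"""Plain-text readers/writers: Newick, FASTA, relaxed PHYLIP, NEXUS, partitions.

NEXUS matrices carry a charset per gene block and, for weighted MRP, a
PAUP*-compatible assumptions block with a weight set, so outputs can be fed
directly to external tree-search tools.  Missing data is always '?' (no
gap characters are ever written; simulated data are gapless).
"""

from __future__ import annotations

import csv
from pathlib import Path

import dendropy

from smidgen.gene_presence import GenePresence
from smidgen.mrp import MISSING, MRPMatrix


def write_newick(tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_newick_list(path) -> list:
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)


def write_fasta(rows: dict, path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for name in rows:
            fh.write(f">{name}\n")
            seq = rows[name]
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fasta(path) -> dict:
    rows: dict[str, list] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                rows[name] = []
            else:
                rows[name].append(line)
    return {k: "".join(v) for k, v in rows.items()}


def write_phylip(rows: dict, path) -> None:
    """Relaxed PHYLIP: full taxon names, two-space separated."""
    taxa = list(rows)
    width = max(len(t) for t in taxa)
    length = len(next(iter(rows.values())))
    with open(path, "w") as fh:
        fh.write(f" {len(taxa)} {length}\n")
        for t in taxa:
            fh.write(f"{t:<{width}}  {rows[t]}\n")


def write_nexus(
    rows: dict,
    path,
    charsets=None,
    datatype: str = "dna",
    symbols: str | None = None,
    weights=None,
) -> None:
    """NEXUS data matrix with optional charsets and a PAUP* weight set."""
    taxa = list(rows)
    length = len(next(iter(rows.values())))
    width = max(len(t) for t in taxa)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"    dimensions ntax={len(taxa)} nchar={length};\n")
        fmt = f"datatype={datatype} missing=? gap=-"
        if symbols is not None:
            fmt += f' symbols="{symbols}"'
        fh.write(f"    format {fmt};\n    matrix\n")
        for t in taxa:
            fh.write(f"    {t:<{width}}  {rows[t]}\n")
        fh.write("    ;\nend;\n")
        if charsets:
            fh.write("\nbegin sets;\n")
            for name, start, end in charsets:
                fh.write(f"    charset {name} = {start + 1}-{end};\n")
            fh.write("end;\n")
        if weights is not None:
            fh.write("\nbegin assumptions;\n    wtset smidgen_weights (vector) =\n        ")
            fh.write(" ".join(_format_weight(w) for w in weights))
            fh.write(";\nend;\n")


def _format_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else f"{w:g}"


def write_partitions(blocks, path, datatype: str = "DNA") -> None:
    """RAxML-style partition file: 'DNA, gene = start-end' per block."""
    with open(path, "w") as fh:
        for gene_id, start, end in blocks:
            fh.write(f"{datatype}, {gene_id} = {start + 1}-{end}\n")


def write_mrp_nexus(matrix: MRPMatrix, path) -> None:
    rows = {t: "" for t in matrix.taxa}
    for i, t in enumerate(matrix.taxa):
        rows[t] = "".join(
            "?" if v == MISSING else str(int(v)) for v in matrix.columns[i]
        )
    weights = None
    if not all(float(w) == 1.0 for w in matrix.weights):
        weights = matrix.weights
    write_nexus(rows, path, datatype="standard", symbols="01", weights=weights)


def write_weights_tsv(matrix: MRPMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["character", "weight", "source_tree", "split"])
        for j, (w, (tree_idx, split)) in enumerate(zip(matrix.weights, matrix.provenance)):
            writer.writerow([j, _format_weight(w), tree_idx, ",".join(sorted(split))])


def write_gene_manifest(genes, path) -> None:
    """TSV manifest: id, universal flag, rate class, birth node, nodes, taxa."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["gene_id", "universal", "rate_class", "birth_node", "loss_nodes", "present_nodes", "taxa"]
        )
        for g in genes:
            writer.writerow(
                [
                    g.gene_id,
                    int(g.universal),
                    g.rate_class,
                    g.birth_node,
                    ",".join(sorted(g.loss_nodes)),
                    ",".join(sorted(g.present_nodes)),
                    ",".join(g.taxa),
                ]
            )


def read_gene_manifest(path) -> list:
    genes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genes.append(
                GenePresence(
                    gene_id=row["gene_id"],
                    universal=bool(int(row["universal"])),
                    rate_class=row["rate_class"],
                    birth_node=row["birth_node"],
                    loss_nodes=frozenset(x for x in row["loss_nodes"].split(",") if x),
                    present_nodes=frozenset(x for x in row["present_nodes"].split(",") if x),
                    taxa=tuple(row["taxa"].split(",")),
                )
            )
    return genes


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
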