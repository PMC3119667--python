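"""Readers and writers for the pipeline's exchange formats.

Formats are deliberately plain: newick for the species tree, FASTA for
gene sequences, and fixed-column TSV dialects for everything else, so that
every stage artifact is diffable and an external pairwise ortholog
assignment tool's output can be dropped in by file substitution.

TSV dialects
------------
genes.tsv               gene_id  genome  chrom  position  strand
similarity.tsv          gene_a  gene_b  score
orthologs.<A>_<B>.tsv   gene_a  gene_b  score          (genomes from filename)
families.tsv            family_id  gene_id  genome
sogs.tsv                sog_id  family_id  genome  gene_id
groups.tsv              group_id  genome  gene_id
events.tsv              family_id  tog_index  parent_node  child_node  kind
labelings.tsv           family_id  tog_index  node_id  label
truth_events.tsv        branch_child  kind  family_id  lineage_id
"""

from __future__ import annotations

import os
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import EventRecord, Gene, Genome, OrthologGroup, PairwiseOrthologSet, SOG, SpeciesTree

__all__ = [
    "read_species_tree",
    "write_species_tree",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
    "attach_sequences",
    "read_similarity",
    "write_similarity",
    "read_pairwise_orthologs",
    "write_pairwise_orthologs",
    "read_families",
    "write_families",
    "read_sogs",
    "write_sogs",
    "read_groups",
    "write_groups",
    "read_truth_events",
]


# ---------------------------------------------------------------------------
# species tree


def read_species_tree(path: str | Path) -> SpeciesTree:
    """Parse a rooted binary newick tree; leaf names become genome ids.

    Non-binary nodes and duplicate leaf names are rejected.  Node indexing
    of the result is deterministic post-order.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf name in species tree: {e.message}") from e

    def convert(node):
        kids = node.child_nodes()
        if not kids:
            label = node.taxon.label if node.taxon else node.label
            if not label:
                raise ValueError("unnamed leaf in species tree")
            return label
        if len(kids) != 2:
            raise ValueError(f"non-binary node with {len(kids)} children in species tree")
        return (convert(kids[0]), convert(kids[1]))

    nested = convert(tree.seed_node)
    if not isinstance(nested, tuple):
        raise ValueError("species tree must have at least 2 leaves")
    return SpeciesTree.from_nested(nested)


def write_species_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# gene tables & sequences

_GENE_COLS = ["gene_id", "genome", "chrom", "position", "strand"]


def read_gene_table(path: str | Path) -> list[Genome]:
    """Read genes.tsv into per-genome ordered gene lists.

    Gaps in position values are allowed; rank order within a chromosome is
    what matters downstream.  Duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "genome": str, "chrom": str})
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"genes table missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id: {dup}")
    genomes = []
    for gid, sub in df.groupby("genome", sort=True):
        genes = [
            Gene(r.gene_id, r.genome, r.chrom, int(r.position), int(r.strand))
            for r in sub.itertuples()
        ]
        genomes.append(Genome(gid, genes))
    return genomes


def write_gene_table(genomes: list[Genome], path: str | Path) -> None:
    rows = [
        (g.id, gene.id, gene.chrom, gene.position, gene.strand)
        for g in sorted(genomes, key=lambda g: g.id)
        for gene in g.genes()
    ]
    df = pd.DataFrame(
        [(r[1], r[0], r[2], r[3], r[4]) for r in rows], columns=_GENE_COLS
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def attach_sequences(genomes: list[Genome], sequences: dict[str, str]) -> list[Genome]:
    """Return genomes with gene sequences filled in from a FASTA mapping."""
    out = []
    for g in genomes:
        genes = []
        for gene in g.genes():
            seq = sequences.get(gene.id)
            genes.append(Gene(gene.id, gene.genome, gene.chrom, gene.position, gene.strand, seq))
        out.append(Genome(g.id, genes))
    return out


# ---------------------------------------------------------------------------
# similarity & pairwise orthologs


def read_similarity(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [(r.gene_a, r.gene_b, float(r.score)) for r in df.itertuples()]


def write_similarity(edges: list[tuple[str, str, float]], path: str | Path) -> None:
    df = pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b", "score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _ortholog_filename(genome_a: str, genome_b: str) -> str:
    a, b = sorted([genome_a, genome_b])
    return f"orthologs.{a}_{b}.tsv"


def read_pairwise_orthologs(paths: list[str | Path]) -> PairwiseOrthologSet:
    """Read per-genome-pair ortholog TSVs into one validated set.

    Each file name encodes its genome pair (``orthologs.<A>_<B>.tsv``).  A
    gene paired twice against the same genome violates the one-to-one
    orthology contract and is rejected.
    """
    out = PairwiseOrthologSet()
    for path in paths:
        name = os.path.basename(str(path))
        stem = name.removeprefix("orthologs.").removesuffix(".tsv")
        try:
            genome_a, genome_b = stem.split("_", 1)
        except ValueError:
            raise ValueError(f"cannot parse genome pair from filename: {name}")
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        for r in df.itertuples():
            out.add(r.gene_a, genome_a, r.gene_b, genome_b, float(r.score))
    return out


def write_pairwise_orthologs(pairs: PairwiseOrthologSet, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_pair: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for ga, a, gb, b, s in sorted(pairs.records):
        by_pair.setdefault((ga, gb), []).append((a, b, s))
    written = []
    for (ga, gb), rows in sorted(by_pair.items()):
        path = outdir / _ortholog_filename(ga, gb)
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# families / SOGs / groups / events


def write_families(families, path: str | Path) -> None:
    rows = [
        (f.id, gene, genome)
        for f in families
        for genome in sorted(f.members)
        for gene in f.members[genome]
    ]
    pd.DataFrame(sorted(rows), columns=["family_id", "gene_id", "genome"]).to_csv(
        path, sep="\t", index=False
    )


def read_families(path: str | Path):
    from .model import GeneFamily

    df = pd.read_csv(path, sep="\t", dtype=str)
    fams = []
    for fid, sub in df.groupby("family_id", sort=True):
        members: dict[str, list[str]] = {}
        for r in sub.itertuples():
            members.setdefault(r.genome, []).append(r.gene_id)
        fams.append(GeneFamily(fid, {g: sorted(v) for g, v in members.items()}))
    return fams


def write_sogs(sogs: list[SOG], path: str | Path) -> None:
    rows = [
        (s.id, s.family_id, genome, s.genes[genome]) for s in sogs for genome in sorted(s.genes)
    ]
    pd.DataFrame(sorted(rows), columns=["sog_id", "family_id", "genome", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_sogs(path: str | Path) -> list[SOG]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for (sid, fid), sub in df.groupby(["sog_id", "family_id"], sort=True):
        out.append(SOG(sid, fid, {r.genome: r.gene_id for r in sub.itertuples()}))
    return out


def write_groups(groups: list[OrthologGroup], events: list[EventRecord], outdir: str | Path) -> None:
    """Write groups.tsv and events.tsv with stable sort order.

    Output is byte-reproducible given identical input: rows are fully
    sorted before writing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    group_rows = sorted(
        (g.id, genome, g.genes[genome]) for g in groups for genome in sorted(g.genes)
    )
    pd.DataFrame(group_rows, columns=["group_id", "genome", "gene_id"]).to_csv(
        outdir / "groups.tsv", sep="\t", index=False
    )
    event_rows = sorted(
        (e.family_id, e.tog_index, e.parent_node, e.child_node, e.kind) for e in events
    )
    pd.DataFrame(
        event_rows, columns=["family_id", "tog_index", "parent_node", "child_node", "kind"]
    ).to_csv(outdir / "events.tsv", sep="\t", index=False)


def read_groups(path: str | Path) -> list[dict[str, str]]:
    """Read a groups/truth_groups TSV as a list of {genome: gene_id} maps."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, sub in df.groupby("group_id", sort=True):
        out.append({r.genome: r.gene_id for r in sub.itertuples()})
    return out


def read_events(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "kind": str})
    return [
        EventRecord(r.family_id, int(r.tog_index), int(r.parent_node), int(r.child_node), r.kind)
        for r in df.itertuples()
    ]


def read_truth_events(path: str | Path) -> list[tuple[int, str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"kind": str, "family_id": str, "lineage_id": str})
    df = df.fillna("")
    return [(int(r.branch_child), r.kind, r.family_id, r.lineage_id) for r in df.itertuples()]


def write_truth_events(events: list[tuple[int, str, str, str]], path: str | Path) -> None:
    pd.DataFrame(
        sorted(events), columns=["branch_child", "kind", "family_id", "lineage_id"]
    ).to_csv(path, sep="\t", index=False)


def write_truth_groups(groups: dict[str, dict[str, str]], path: str | Path) -> None:
    rows = sorted(
        (lin, genome, gene) for lin, members in groups.items() for genome, gene in members.items()
    )
    pd.DataFrame(rows, columns=["group_id", "genome", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_labelings(solutions: dict, path: str | Path) -> None:
    """solutions: family id -> LabelingSolution (labels shape (K, n_nodes))."""
    rows = []
    for fid, sol in sorted(solutions.items()):
        K, n = sol.labels.shape
        for k in range(K):
            for v in range(n):
                rows.append((fid, k, v, int(sol.labels[k, v])))
    pd.DataFrame(rows, columns=["family_id", "tog_index", "node_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_labelings(path: str | Path) -> dict[str, "np.ndarray"]:
    import numpy as np

    df = pd.read_csv(path, sep="\t", dtype={"family_id": str})
    out = {}
    for fid, sub in df.groupby("family_id", sort=True):
        K = int(sub["tog_index"].max()) + 1
        n = int(sub["node_id"].max()) + 1
        labels = np.zeros((K, n), dtype=np.int8)
        for r in sub.itertuples():
            labels[int(r.tog_index), int(r.node_id)] = int(r.label)
        out[fid] = labels
    return out
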