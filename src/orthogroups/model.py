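"""Shared domain types for the multi-genome ortholog-group pipeline.

The pipeline compares N genomes on a rooted binary species tree.  Gene
families (all homologs across all genomes) are partitioned into *super
ortholog groups* (SOGs) holding at most one gene per genome; each SOG is
viewed as a *tree of ortholog groups* (TOG): the species tree with binary
leaf labels marking which genomes contribute a gene.  Internal-node labels
are inferred by minimum-flip parsimony and ortholog groups and gene
birth/duplication/loss events read off the labeled trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeciesTree",
    "Gene",
    "Genome",
    "GeneFamily",
    "PairwiseOrthologSet",
    "SOG",
    "OrthologGroup",
    "EventRecord",
]


class SpeciesTree:
    """Rooted binary tree over genome identifiers, indexed in post-order.

    Nodes are integers ``0 .. 2N-2`` for ``N`` leaves; children always carry
    lower indices than their parent and the root is node ``2N-2``.  Leaves
    are named by genome id.  This single scaffold is shared by every TOG.

    Parameters
    ----------
    parent : sequence of int
        Parent index per node (``-1`` for the root).
    children : sequence of tuple or None
        ``(left, right)`` per internal node, ``None`` per leaf.
    names : sequence of str or None
        Genome id per leaf, ``None`` per internal node.
    """

    __slots__ = ("parent", "children", "names", "n_nodes", "n_leaves", "root", "leaf_of")

    def __init__(self, parent, children, names):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = list(children)
        self.names = list(names)
        self.n_nodes = len(self.names)
        if self.n_nodes % 2 != 1:
            raise ValueError("a rooted binary tree has an odd node count (2N-1)")
        self.n_leaves = (self.n_nodes + 1) // 2
        self.root = self.n_nodes - 1
        self.leaf_of = {}
        for i, ch in enumerate(self.children):
            if ch is None:
                name = self.names[i]
                if name in self.leaf_of:
                    raise ValueError(f"duplicate leaf name: {name!r}")
                self.leaf_of[name] = i
        if len(self.leaf_of) != self.n_leaves:
            raise ValueError("leaf count does not match node count")
        # children-before-parent is what post-order indexing means here
        for i, ch in enumerate(self.children):
            if ch is not None and max(ch) >= i:
                raise ValueError("node indexing is not post-order")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_nested(cls, nested) -> "SpeciesTree":
        """Build from a nested structure: a leaf name, or a 2-tuple of them."""
        parent: list[int] = []
        children: list = []
        names: list = []

        def build(x) -> int:
            if isinstance(x, tuple):
                if len(x) != 2:
                    raise ValueError(f"non-binary node with {len(x)} children")
                left = build(x[0])
                right = build(x[1])
                idx = len(names)
                names.append(None)
                children.append((left, right))
                parent.append(-1)
                parent[left] = idx
                parent[right] = idx
                return idx
            idx = len(names)
            names.append(str(x))
            children.append(None)
            parent.append(-1)
            return idx

        build(nested)
        return cls(parent, children, names)

    # -- traversal helpers ----------------------------------------------

    def leaves(self) -> list[int]:
        return [i for i, c in enumerate(self.children) if c is None]

    def postorder(self) -> range:
        """Node indices in post-order (indices *are* post-order ranks)."""
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def edges(self) -> list[tuple[int, int]]:
        """All (parent, child) edges."""
        return [(int(self.parent[v]), v) for v in range(self.n_nodes) if v != self.root]

    def is_leaf(self, v: int) -> bool:
        return self.children[v] is None

    def subtree_leaves(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            c = self.children[u]
            if c is None:
                out.append(u)
            else:
                stack.extend(c)
        return sorted(out)

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            c = self.children[v]
            if c is None:
                return self.names[v]
            return f"({fmt(c[0])},{fmt(c[1])})"

        return fmt(self.root) + ";"

    def genomes(self) -> list[str]:
        """Genome ids in leaf post-order."""
        return [self.names[i] for i in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({self.to_newick()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesTree) and self.to_newick() == other.to_newick()


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with its location on a genome.

    ``position`` is a 0-based rank within the chromosome; ``strand`` is +1
    or -1.  The sequence (nucleotide or protein) is optional and only needed
    by the similarity scorer.
    """

    id: str
    genome: str
    chrom: str
    position: int
    strand: int
    sequence: str | None = None


class Genome:
    """A genome snapshot: ordered gene lists per chromosome."""

    def __init__(self, id: str, genes: list[Gene]):
        self.id = id
        self.chromosomes: dict[str, list[Gene]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.position)):
            if g.genome != id:
                raise ValueError(f"gene {g.id} belongs to genome {g.genome}, not {id}")
            self.chromosomes.setdefault(g.chrom, []).append(g)
        # normalize positions to consecutive ranks
        for chrom, glist in self.chromosomes.items():
            self.chromosomes[chrom] = [
                Gene(g.id, g.genome, g.chrom, rank, g.strand, g.sequence)
                for rank, g in enumerate(glist)
            ]

    def genes(self) -> list[Gene]:
        return [g for glist in self.chromosomes.values() for g in glist]

    def __len__(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Genome({self.id!r}, {len(self)} genes)"


@dataclass
class GeneFamily:
    """All homologous genes across the compared genomes (one clustering unit)."""

    id: str
    members: dict[str, list[str]]  # genome -> sorted gene ids

    def genes(self) -> list[str]:
        return [g for gs in self.members.values() for g in gs]

    def size(self) -> int:
        return sum(len(gs) for gs in self.members.values())

    def n_max(self) -> int:
        """Largest per-genome paralog count."""
        return max((len(gs) for gs in self.members.values()), default=0)


class PairwiseOrthologSet:
    """One-to-one ortholog assignments between genome pairs, with bit scores.

    A gene may appear in at most one pair against each other genome; adding
    a violating pair raises ``ValueError``.
    """

    def __init__(self):
        # (gene, other_genome) -> (partner_gene, score)
        self._partner: dict[tuple[str, str], tuple[str, float]] = {}
        # canonical records: (genome_a, gene_a, genome_b, gene_b, score), genome_a < genome_b
        self.records: list[tuple[str, str, str, str, float]] = []

    def add(self, gene_a: str, genome_a: str, gene_b: str, genome_b: str, score: float):
        if genome_a == genome_b:
            raise ValueError(f"ortholog pair within one genome: {gene_a}, {gene_b}")
        if (gene_a, genome_b) in self._partner:
            raise ValueError(f"gene {gene_a} paired twice against genome {genome_b}")
        if (gene_b, genome_a) in self._partner:
            raise ValueError(f"gene {gene_b} paired twice against genome {genome_a}")
        self._partner[(gene_a, genome_b)] = (gene_b, float(score))
        self._partner[(gene_b, genome_a)] = (gene_a, float(score))
        if genome_a > genome_b:
            genome_a, gene_a, genome_b, gene_b = genome_b, gene_b, genome_a, gene_a
        self.records.append((genome_a, gene_a, genome_b, gene_b, float(score)))

    def partner(self, gene: str, other_genome: str) -> tuple[str, float] | None:
        return self._partner.get((gene, other_genome))

    def update(self, other: "PairwiseOrthologSet"):
        for ga, a, gb, b, s in other.records:
            self.add(a, ga, b, gb, s)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class SOG:
    """Super ortholog group: at most one gene per genome within one family."""

    id: str
    family_id: str
    genes: dict[str, str]  # genome -> gene id

    def __post_init__(self):
        if not self.genes:
            raise ValueError("a SOG must contain at least one gene")


@dataclass
class OrthologGroup:
    """Genes at the 1-labeled leaves under one anchor node of a labeled TOG."""

    id: str
    family_id: str
    tog_index: int
    anchor: int  # species-tree node index of the highest 1-labeled node
    genes: dict[str, str]  # genome -> gene id


@dataclass(frozen=True)
class EventRecord:
    """One inferred evolutionary event on a species-tree edge of a TOG."""

    family_id: str
    tog_index: int
    parent_node: int
    child_node: int
    kind: str  # birth | duplication | loss

    KINDS = ("birth", "duplication", "loss")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown event kind: {self.kind}")
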