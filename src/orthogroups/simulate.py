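"""Genome-evolution simulator with tracked ortholog-group ground truth.

Generates N contemporary single-chromosome genomes by evolving a root
genome of random coding-like genes down a random rooted binary species
tree.  Along every branch (speciation edge) a fixed number M of genome
events is drawn — gene duplications (half tandem), gene births, gene
losses and segment reversals — interleaved with M+1 equal substitution
epochs under a Jukes-Cantor nucleotide model totalling a prescribed
expected number of substitutions per site, so all genes tick to the same
molecular clock between genome events.

Ground truth uses gene *lineages*: a speciation copies lineage ids, a
duplication assigns a fresh lineage to the new copy (the original keeps
its id, a parent-daughter asymmetry), and a birth opens a fresh lineage
and a fresh family.  The true ortholog groups are exactly the lineages
with at least two leaf genes — direct descendants of one ancestral gene
never separated by a duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Gene, Genome, SpeciesTree

__all__ = ["SimulationParams", "TruthRecord", "random_species_tree", "mutate_sequences", "evolve"]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA
_SENSE = np.array(
    [(a, b, c) for a in range(4) for b in range(4) for c in range(4) if (a, b, c) not in _STOPS],
    dtype=np.uint8,
)


@dataclass
class SimulationParams:
    """The six model parameters plus fixed structural settings.

    ``events_per_branch`` (M) events are applied on every speciation
    branch, split into duplications, births, losses and (the remainder)
    reversals by the three fractions.  ``branch_length`` is the expected
    number of substitutions per site accumulated along one branch.
    """

    n_species: int = 5
    events_per_branch: int = 20
    branch_length: float = 0.02
    p_dup: float = 0.4
    p_birth: float = 0.2
    p_loss: float = 0.2
    tandem_fraction: float = 0.5
    root_genes: int = 100
    gene_length_nt: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.events_per_branch < 0 or self.branch_length < 0:
            raise ValueError("event count and branch length must be non-negative")
        fracs = (self.p_dup, self.p_birth, self.p_loss, self.tandem_fraction)
        if any(not 0 <= p <= 1 for p in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.p_dup + self.p_birth + self.p_loss > 1 + 1e-12:
            raise ValueError("event fractions must sum to at most 1")
        if self.gene_length_nt % 3:
            raise ValueError("gene length must be divisible by 3")

    @property
    def p_reversal(self) -> float:
        return max(0.0, 1.0 - self.p_dup - self.p_birth - self.p_loss)


@dataclass
class TruthRecord:
    """Simulator ground truth: true groups, event log, and provenance maps."""

    tree: SpeciesTree
    groups: dict[str, dict[str, str]]  # lineage id -> {genome: gene id}, size >= 2
    events: list[tuple[int, str, str, str]]  # (branch child node, kind, family, lineage)
    family_of: dict[str, str]  # leaf gene id -> true family id
    lineage_of: dict[str, str]  # leaf gene id -> lineage id


def random_species_tree(n_species: int, seed: int | np.random.Generator) -> SpeciesTree:
    """Uniformly random rooted binary topology over leaves S1..Sn.

    Built by sequential random attachment: each new leaf subdivides one of
    the 2m-2 existing edges or is joined above the root (2m-1 equally
    likely placements for an m-leaf tree), which yields the uniform
    distribution over rooted binary topologies.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nested: object = ("S1", "S2")

    def attach(sub, path: list[int], leaf: str):
        if not path:
            return (sub, leaf)
        head, *rest = path
        if head == 0:
            return (attach(sub[0], rest, leaf), sub[1])
        return (sub[0], attach(sub[1], rest, leaf))

    def edge_paths(sub, prefix=()) -> list[tuple]:
        # path to every node (= the edge above it); () is the root position
        out = [prefix]
        if isinstance(sub, tuple):
            out += edge_paths(sub[0], prefix + (0,))
            out += edge_paths(sub[1], prefix + (1,))
        return out

    for i in range(3, n_species + 1):
        paths = edge_paths(nested)
        choice = paths[int(rng.integers(len(paths)))]
        nested = attach(nested, list(choice), f"S{i}")
    return SpeciesTree.from_nested(nested)


# ---------------------------------------------------------------------------
# sequences


def _random_gene_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    codons = _SENSE[rng.integers(len(_SENSE), size=length // 3)]
    return codons.reshape(-1)


def _jc_mutate(mat: np.ndarray, t: float, rng: np.random.Generator) -> None:
    """In-place Jukes-Cantor substitution over an (n_genes, L) base-code
    matrix for expected ``t`` substitutions per site."""
    if t <= 0 or mat.size == 0:
        return
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    mask = rng.random(mat.shape) < p
    n = int(mask.sum())
    if n:
        mat[mask] = (mat[mask] + rng.integers(1, 4, size=n)) % 4


def mutate_sequences(genes: list[str], epoch_length: float, seed: int | np.random.Generator) -> list[str]:
    """Apply independent-site Jukes-Cantor substitution to each sequence.

    ``epoch_length`` is the expected number of substitutions per site;
    lengths are preserved.  The expected observed difference fraction is
    ``3/4 (1 - exp(-4t/3))``.
    """
    if epoch_length < 0:
        raise ValueError("epoch length must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        code[b] = i
    out = []
    for s in genes:
        arr = code[np.frombuffer(s.encode(), dtype=np.uint8)].copy()
        if (arr == 255).any():
            raise ValueError("sequence contains non-ACGT characters")
        mat = arr[None, :]
        _jc_mutate(mat, epoch_length, rng)
        out.append(_BASES[mat[0]].tobytes().decode())
    return out


# ---------------------------------------------------------------------------
# evolution


@dataclass
class _SimGene:
    uid: int
    lineage: int
    family: int
    strand: int
    seq: np.ndarray

    def copy(self) -> "_SimGene":
        return _SimGene(self.uid, self.lineage, self.family, self.strand, self.seq.copy())


class _Counter:
    def __init__(self, start: int):
        self.n = start

    def next(self) -> int:
        self.n += 1
        return self.n - 1


def _mutate_genome(genes: list[_SimGene], t: float, rng: np.random.Generator) -> None:
    if not genes or t <= 0:
        return
    mat = np.stack([g.seq for g in genes])
    _jc_mutate(mat, t, rng)
    for g, row in zip(genes, mat):
        g.seq = row


def _apply_event(
    genes: list[_SimGene],
    kind: str,
    params: SimulationParams,
    rng: np.random.Generator,
    uid_c: _Counter,
    lin_c: _Counter,
    fam_c: _Counter,
) -> tuple[str, int, int] | None:
    """Mutates ``genes`` in place; returns (kind, family, lineage) or None for a no-op."""
    if kind == "duplication":
        if not genes:
            logger.warning("duplication on empty genome skipped")
            return None
        i = int(rng.integers(len(genes)))
        src = genes[i]
        copy = _SimGene(uid_c.next(), lin_c.next(), src.family, src.strand, src.seq.copy())
        if rng.random() < params.tandem_fraction:
            genes.insert(i + 1, copy)  # tandem: immediately 3' of the source
        else:
            genes.insert(int(rng.integers(len(genes) + 1)), copy)
        return ("duplication", copy.family, copy.lineage)
    if kind == "birth":
        g = _SimGene(
            uid_c.next(), lin_c.next(), fam_c.next(), 1, _random_gene_seq(params.gene_length_nt, rng)
        )
        genes.insert(int(rng.integers(len(genes) + 1)), g)
        return ("birth", g.family, g.lineage)
    if kind == "loss":
        if not genes:
            logger.warning("gene loss on empty genome treated as no-op")
            return None
        i = int(rng.integers(len(genes)))
        g = genes.pop(i)
        return ("loss", g.family, g.lineage)
    if kind == "reversal":
        if len(genes) >= 2:
            i, j = sorted(rng.integers(len(genes) + 1, size=2))
            if j - i >= 2:
                seg = genes[i:j][::-1]
                for g in seg:
                    g.strand = -g.strand
                genes[i:j] = seg
        return ("reversal", "", "")
    raise ValueError(f"unknown event kind: {kind}")


def evolve(params: SimulationParams, tree: SpeciesTree | None = None) -> tuple[list[Genome], TruthRecord]:
    """Simulate genome evolution down the species tree.

    Returns the leaf genomes (with sequences) and the ground truth.  If no
    tree is given a random one is drawn from the same seed.  Identical
    params (and tree) yield byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    if tree is None:
        tree = random_species_tree(params.n_species, rng)
    elif tree.n_leaves != params.n_species:
        raise ValueError("tree leaf count does not match n_species")

    uid_c, lin_c, fam_c = _Counter(0), _Counter(0), _Counter(0)
    root_genome = [
        _SimGene(uid_c.next(), lin_c.next(), fam_c.next(), 1, _random_gene_seq(params.gene_length_nt, rng))
        for _ in range(params.root_genes)
    ]

    M = params.events_per_branch
    kinds = ["duplication", "birth", "loss", "reversal"]
    probs = [params.p_dup, params.p_birth, params.p_loss, params.p_reversal]
    epoch = params.branch_length / (M + 1)

    events: list[tuple[int, str, str, str]] = []
    leaf_genes: dict[int, list[_SimGene]] = {}

    def descend(node: int, genes: list[_SimGene]) -> None:
        c = tree.children[node]
        if c is None:
            leaf_genes[node] = genes
            return
        for child in c:
            branch = [g.copy() for g in genes]
            drawn = [kinds[int(t)] for t in rng.choice(4, size=M, p=probs)]
            _mutate_genome(branch, epoch, rng)
            for kind in drawn:
                rec = _apply_event(branch, kind, params, rng, uid_c, lin_c, fam_c)
                if rec is not None and rec[0] != "reversal":
                    events.append((child, rec[0], f"tf{rec[1]:05d}", f"ln{rec[2]:06d}"))
                elif rec is not None:
                    events.append((child, "reversal", "", ""))
                _mutate_genome(branch, epoch, rng)
            descend(child, branch)

    descend(tree.root, root_genome)

    genomes: list[Genome] = []
    lineage_members: dict[str, dict[str, str]] = {}
    family_of: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    for leaf in tree.leaves():
        species = tree.names[leaf]
        out_genes = []
        for pos, g in enumerate(leaf_genes[leaf]):
            gid = f"{species}_g{g.uid:05d}"
            seq = _BASES[g.seq].tobytes().decode()
            out_genes.append(Gene(gid, species, "chr1", pos, g.strand, seq))
            lin = f"ln{g.lineage:06d}"
            lineage_members.setdefault(lin, {})[species] = gid
            family_of[gid] = f"tf{g.family:05d}"
            lineage_of[gid] = lin
        genomes.append(Genome(species, out_genes))

    groups = {
        lin: members for lin, members in sorted(lineage_members.items()) if len(members) >= 2
    }
    truth = TruthRecord(tree, groups, events, family_of, lineage_of)
    return genomes, truth
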