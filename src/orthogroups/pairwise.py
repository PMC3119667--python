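"""Bidirectional-best-hit stand-in for external pairwise ortholog input.

The pipeline normally consumes one-to-one ortholog pairs produced by a
dedicated rearrangement-aware pairwise tool; this module provides a
closed-loop replacement for simulated data.  Within each family and
genome pair it selects mutual best hits by similarity score and then
greedily pairs the remaining genes by descending score, so the output
always satisfies the one-to-one invariant.

A pure-score best hit cannot separate a recently duplicated gene from its
source copy: both are equidistant in expectation from any ortholog in a
third genome.  The tool this module stands in for resolves that ambiguity
from gene order, so candidate ranking here adds two gene-order terms to
the bit score: a bonus for shared flanking-gene families (a displaced
duplicate sits in the wrong neighbourhood) and a penalty on a gene's rank
within a tandem array of same-family genes (the ancestral copy is taken to
be the array's first member, matching the simulator's convention of
inserting tandem duplicates 3' of their source).  Both terms are
scale-separated: far smaller than the score gap between correct and
incorrect family members, larger than mutation noise between
near-identical copies.  Remaining ties break on gene id.
"""

from __future__ import annotations

from .families import SimilarityGraph
from .model import GeneFamily, Genome, PairwiseOrthologSet

__all__ = ["bbh_orthologs", "neighbor_context"]


def neighbor_context(
    genome: Genome, family_of: dict[str, str], window: int = 4
) -> dict[str, frozenset]:
    """Per gene: the set of families of up to ``window`` flanking genes on
    each side, skipping genes of its own family (tandem copies would
    otherwise blur the context).  Robust to reversals away from segment
    boundaries since the set is unordered."""
    out: dict[str, frozenset] = {}
    for glist in genome.chromosomes.values():
        fams = [family_of.get(g.id) for g in glist]
        for i, g in enumerate(glist):
            own = family_of.get(g.id)
            ctx = []
            for step in (-1, 1):
                j, found = i + step, 0
                while 0 <= j < len(glist) and found < window:
                    if fams[j] is not None and fams[j] != own:
                        ctx.append(fams[j])
                        found += 1
                    j += step
            out[g.id] = frozenset(ctx)
    return out


def tandem_rank(genome: Genome, family_of: dict[str, str], window: int = 3) -> dict[str, int]:
    """Per gene: the number of same-family genes within ``window`` positions
    on its lower-coordinate (5') side; 0 for genes outside tandem arrays."""
    out: dict[str, int] = {}
    for glist in genome.chromosomes.values():
        for i, g in enumerate(glist):
            own = family_of.get(g.id)
            out[g.id] = sum(
                1 for j in range(max(0, i - window), i) if family_of.get(glist[j].id) == own
            )
    return out


def bbh_orthologs(
    family: GeneFamily,
    graph: SimilarityGraph,
    genome_a: Genome,
    genome_b: Genome,
    family_of: dict[str, str] | None = None,
    context_bonus: float = 100.0,
    tandem_penalty: float = 100.0,
    position_epsilon: float = 1e-3,
) -> PairwiseOrthologSet:
    """One-to-one ortholog pairs between two genomes within one family.

    Mutual best hits (on the adjusted score) are taken first; remaining
    genes are greedily paired by descending adjusted score.  Swapping the
    genome arguments yields the same pair set.  Reported pair scores are
    the raw similarity scores.
    """
    if genome_a.id == genome_b.id:
        raise ValueError("genome pair must be two distinct genomes")
    # canonical orientation for determinism under argument swap
    if genome_a.id > genome_b.id:
        genome_a, genome_b = genome_b, genome_a
    genes_a = sorted(family.members.get(genome_a.id, ()))
    genes_b = sorted(family.members.get(genome_b.id, ()))
    out = PairwiseOrthologSet()
    if not genes_a or not genes_b:
        return out

    ctx_a = neighbor_context(genome_a, family_of) if family_of else {}
    ctx_b = neighbor_context(genome_b, family_of) if family_of else {}
    ranks = {}
    if family_of:
        ranks.update(tandem_rank(genome_a, family_of))
        ranks.update(tandem_rank(genome_b, family_of))
    pos = {
        g.id: g.position
        for gn in (genome_a, genome_b)
        for g in gn.genes()
    }

    edges: dict[tuple[str, str], tuple[float, float]] = {}  # (a, b) -> (adjusted, raw)
    for a in genes_a:
        for b in genes_b:
            raw = graph.weight(a, b)
            if raw is None:
                continue
            adj = raw
            if family_of:
                adj += context_bonus * len(ctx_a.get(a, frozenset()) & ctx_b.get(b, frozenset()))
                adj -= tandem_penalty * (ranks.get(a, 0) + ranks.get(b, 0))
            adj -= position_epsilon * (pos.get(a, 0) + pos.get(b, 0))
            edges[(a, b)] = (adj, raw)
    if not edges:
        return out

    def best(cands: list[tuple[str, float]]) -> str:
        # highest adjusted score; ties on lexicographically smaller id
        return min(cands, key=lambda t: (-t[1], t[0]))[0]

    best_of_a = {
        a: best([(b, edges[(a, b)][0]) for b in genes_b if (a, b) in edges])
        for a in genes_a
        if any((a, b) in edges for b in genes_b)
    }
    best_of_b = {
        b: best([(a, edges[(a, b)][0]) for a in genes_a if (a, b) in edges])
        for b in genes_b
        if any((a, b) in edges for a in genes_a)
    }
    used_a, used_b = set(), set()
    for a in genes_a:
        b = best_of_a.get(a)
        if b is not None and best_of_b.get(b) == a:
            out.add(a, genome_a.id, b, genome_b.id, edges[(a, b)][1])
            used_a.add(a)
            used_b.add(b)
    # greedy completion by descending adjusted score, then ids
    rest = sorted(
        ((adj, a, b) for (a, b), (adj, _raw) in edges.items()),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for adj, a, b in rest:
        if a in used_a or b in used_b:
            continue
        out.add(a, genome_a.id, b, genome_b.id, edges[(a, b)][1])
        used_a.add(a)
        used_b.add(b)
    return out
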