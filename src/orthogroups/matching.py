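"""Partition of gene families into super ortholog groups (SOGs).

Each family spans N genomes with possibly several paralogs per genome.
Finding the maximum-weight perfect N-dimensional matching that groups the
genes into SOGs is NP-hard for N >= 3, so the family is treated as an
N-stage graph (one stage per genome, padded with dummy vertices to equal
size) and stages are merged pairwise with the Hungarian algorithm.  The
merge order follows a post-order traversal of the species tree, so a stage
is always combined with a stage close to it phylogenetically.

Edge weights are the similarity bit scores of the externally supplied
one-to-one ortholog pairs; absent edges and dummy vertices weigh 0, which
is neutral for maximization and lets dummies absorb unmatched genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import GeneFamily, PairwiseOrthologSet, SOG, SpeciesTree

__all__ = ["MultipartiteGraph", "build_multipartite", "hungarian_max", "partition_family"]

logger = logging.getLogger(__name__)


@dataclass
class MultipartiteGraph:
    """N-stage graph for one family: per-genome vertex lists padded to n_max.

    ``stages`` maps genome -> list of gene ids padded with ``None`` dummies;
    ``weights`` holds bit scores keyed by frozenset({gene_a, gene_b}) for
    the family's ortholog pairs only.  Any other cross-stage pair weighs 0.
    """

    family_id: str
    stages: dict[str, list[str | None]]
    weights: dict[frozenset, float]
    n_max: int

    def weight(self, a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        return self.weights.get(frozenset((a, b)), 0.0)


def build_multipartite(
    family: GeneFamily, pairwise: PairwiseOrthologSet, tree: SpeciesTree
) -> MultipartiteGraph:
    """Build the padded N-stage graph for one family.

    One stage per species-tree genome (size 0 before padding when the
    family is absent there).  Ortholog pairs that span two families are
    logged and dropped: families are the partition unit.
    """
    if family.size() == 0:
        raise ValueError("family is empty")
    genomes = tree.genomes()
    members = {g: set(family.members.get(g, ())) for g in genomes}
    all_members = set(family.genes())
    n_max = max(len(m) for m in members.values())
    stages: dict[str, list[str | None]] = {}
    for g in genomes:
        stage: list[str | None] = sorted(members[g])
        stage += [None] * (n_max - len(stage))
        stages[g] = stage
    weights: dict[frozenset, float] = {}
    for genome_a, a, genome_b, b, score in pairwise:
        a_in, b_in = a in all_members, b in all_members
        if not (a_in or b_in):
            continue
        if a_in != b_in:
            logger.warning(
                "ortholog pair (%s, %s) spans two families; dropped from family %s",
                a, b, family.id,
            )
            continue
        weights[frozenset((a, b))] = score
    return MultipartiteGraph(family.id, stages, weights, n_max)


def hungarian_max(weights: np.ndarray) -> np.ndarray:
    """Maximum-weight assignment of a square matrix; returns the permutation
    ``perm`` with row i matched to column perm[i]."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.isfinite(w).all():
        raise ValueError("weight matrix must be finite")
    rows, cols = linear_sum_assignment(w, maximize=True)
    perm = np.empty(w.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm


def _split_unsupported(tup: dict[str, str], graph: MultipartiteGraph) -> list[dict[str, str]]:
    """Split a matched tuple into connected components of its positive-weight
    evidence graph.

    Padding forces every gene into some tuple even when no ortholog pair
    supports its membership; asserting orthology with zero evidence would
    silently absorb inparalogs whose true counterpart was lost.  Splitting
    only severs gene pairs with no evidence path, so it never discards
    matched weight.
    """
    items = sorted(tup.items())
    if len(items) <= 1:
        return [dict(items)] if items else []
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if graph.weight(items[i][1], items[j][1]) > 0:
                parent[find(i)] = find(j)
    comps: dict[int, dict[str, str]] = {}
    for i, (genome, gene) in enumerate(items):
        comps.setdefault(find(i), {})[genome] = gene
    return sorted(comps.values(), key=lambda c: sorted(c.values()))


def partition_family(graph: MultipartiteGraph, tree: SpeciesTree) -> list[SOG]:
    """Merge stages in species-tree post-order into SOGs.

    Each species-tree leaf starts with its genome's padded stage as a list
    of single-gene tuples; an internal node merges its children's (possibly
    already merged) stages with a Hungarian assignment on the n_max x n_max
    inter-stage weight matrix, where the weight between two tuples is the
    summed pairwise weight of their non-dummy members.  Final tuples are
    split into connected components of their internal positive-weight
    evidence before, with dummies removed, becoming SOGs (see
    :func:`_split_unsupported`).
    """
    n_max = graph.n_max
    # a merged "vertex" is a dict genome -> gene id (dummies omitted)
    stage_at: dict[int, list[dict[str, str]]] = {}
    for v in tree.postorder():
        c = tree.children[v]
        if c is None:
            genome = tree.names[v]
            stage_at[v] = [
                {} if g is None else {genome: g} for g in graph.stages.get(genome, [None] * n_max)
            ]
            continue
        left, right = stage_at.pop(c[0]), stage_at.pop(c[1])
        w = np.zeros((n_max, n_max))
        for i, tup_a in enumerate(left):
            for j, tup_b in enumerate(right):
                w[i, j] = sum(
                    graph.weight(a, b) for a in tup_a.values() for b in tup_b.values()
                )
        perm = hungarian_max(w)
        stage_at[v] = [{**left[i], **right[perm[i]]} for i in range(n_max)]
    final = [part for t in stage_at[tree.root] for part in _split_unsupported(t, graph)]
    tuples = sorted((t for t in final if t), key=lambda t: sorted(t.values()))
    return [
        SOG(f"{graph.family_id}.{i}", graph.family_id, dict(sorted(t.items())))
        for i, t in enumerate(tuples)
    ]
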