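"""Gene family construction from all-vs-all sequence similarity.

Families are the homology units the rest of the pipeline partitions: all
homologous genes across all genomes.  Two steps mirror the classical
recipe of an all-vs-all protein homology search followed by Markov
clustering (MCL) of the resulting similarity graph:

* :func:`score_all_pairs` computes a symmetric, bit-score-like similarity
  for every sufficiently similar gene pair.  A shared-k-mer prefilter
  (sparse k-mer-presence matrix product) selects candidate pairs, which
  are then globally aligned with edlib; the score ``2*L - 5*d`` (alignment
  span minus a penalized edit distance) is monotone in alignment identity
  and length and drops below any positive threshold for unrelated random
  sequences.
* :func:`mcl_cluster` reimplements Markov clustering: alternate expansion
  (matrix squaring) and inflation (elementwise power + renormalization) of
  the column-stochastic self-loop-augmented weight matrix until a fixed
  point, then read clusters off the attractor structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import scipy.sparse as sp

from .model import GeneFamily, Genome

__all__ = ["SimilarityGraph", "score_pair", "score_all_pairs", "mcl_cluster"]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityGraph:
    """Undirected weighted similarity graph over all genes of all genomes.

    The vertex set includes genes without any edge (isolated genes become
    singleton families).  Weights are positive; no self-edges.
    """

    genes: list[str]
    genome_of: dict[str, str]
    edges: dict[frozenset, float] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, weight: float):
        if a == b:
            raise ValueError("self-edge")
        if weight <= 0:
            raise ValueError("edge weights must be positive")
        self.edges[frozenset((a, b))] = float(weight)

    def weight(self, a: str, b: str) -> float | None:
        return self.edges.get(frozenset((a, b)))

    def neighbors(self) -> dict[str, list[tuple[str, float]]]:
        adj: dict[str, list[tuple[str, float]]] = {g: [] for g in self.genes}
        for e, w in self.edges.items():
            a, b = sorted(e)
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj


def score_pair(seq_a: str, seq_b: str) -> float:
    """Alignment-derived bit-like score: ``2*L - 5*d`` for global edit
    distance d over alignment span L = max(len).  Symmetric; negative for
    unrelated sequences."""
    if not seq_a or not seq_b:
        raise ValueError("cannot score an empty sequence")
    d = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    L = max(len(seq_a), len(seq_b))
    return 2.0 * L - 5.0 * d


def _kmer_matrix(seqs: list[str], k: int) -> sp.csr_matrix:
    """Binary genes x k-mer-code presence matrix (codes hashed into 2^24 buckets)."""
    nbuckets = 1 << 24
    indptr = [0]
    indices: list[np.ndarray] = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int64)
        if arr.shape[0] < k:
            codes = np.empty(0, dtype=np.int64)
        else:
            n = arr.shape[0] - k + 1
            codes = np.zeros(n, dtype=np.int64)
            for i in range(k):
                codes = codes * 131 + arr[i : i + n]
            codes = np.unique(codes % nbuckets)
        indices.append(codes)
        indptr.append(indptr[-1] + codes.shape[0])
    data = np.ones(indptr[-1], dtype=np.int32)
    return sp.csr_matrix(
        (data, np.concatenate(indices) if indices else np.empty(0), np.array(indptr)),
        shape=(len(seqs), nbuckets),
    )


def score_all_pairs(
    genomes: list[Genome],
    min_score: float = 50.0,
    k: int = 12,
    min_shared_kmers: int = 10,
) -> SimilarityGraph:
    """All-vs-all similarity graph over every gene of every genome.

    Every gene must carry a sequence.  Pairs sharing fewer than
    ``min_shared_kmers`` k-mers are treated as unrelated and skipped before
    alignment; scored pairs below ``min_score`` are omitted.
    """
    ids, seqs, genome_of = [], [], {}
    for g in genomes:
        for gene in g.genes():
            if not gene.sequence:
                raise ValueError(f"gene {gene.id} has no sequence")
            ids.append(gene.id)
            seqs.append(gene.sequence)
            genome_of[gene.id] = g.id
    order = np.argsort(ids)
    ids = [ids[i] for i in order]
    seqs = [seqs[i] for i in order]
    graph = SimilarityGraph(ids, genome_of)
    if len(ids) < 2:
        return graph
    X = _kmer_matrix(seqs, k)
    shared = sp.triu(X @ X.T, k=1).tocoo()
    keep = shared.data >= min_shared_kmers
    for i, j in sorted(zip(shared.row[keep].tolist(), shared.col[keep].tolist())):
        s = score_pair(seqs[i], seqs[j])
        if s >= min_score:
            graph.add_edge(ids[i], ids[j], s)
    return graph


def _mcl_matrix(adj: np.ndarray, inflation: float, max_iter: int, tol: float) -> np.ndarray:
    """Iterate Markov clustering on a dense symmetric weight matrix with
    max-incident-weight self-loops until change < tol or max_iter."""
    a = adj.copy()
    np.fill_diagonal(a, a.max(axis=1))
    m = a / a.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        m2 = m @ m
        np.power(m2, inflation, out=m2)
        m2[m2 < 1e-12] = 0.0
        colsum = m2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m2 /= colsum
        delta = np.abs(m2 - m).max()
        m = m2
        if delta < tol:
            return m
    logger.warning("Markov clustering did not converge within %d iterations", max_iter)
    return m


def _clusters_from_limit(m: np.ndarray, totals: np.ndarray, names: list[str]) -> list[list[int]]:
    """Read clusters off the (near-)idempotent limit matrix.

    Attractors are nodes with mass on their own diagonal; attractors
    linked by flow form one cluster; every other node joins the cluster of
    the attractor receiving most of its flow (ties: higher total incident
    weight, then lexicographic gene id).
    """
    eps = 1e-6
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # pathological oscillation: fall back to one cluster
        return [list(range(n))]
    # union attractors connected by flow
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > eps or m[j, i] > eps):
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in attractors:
        clusters.setdefault(find(i), []).append(i)
    attr_set = set(attractors)
    for j in range(n):
        if j in attr_set:
            continue
        flows = m[attractors, j]
        best = max(
            range(len(attractors)),
            key=lambda t: (flows[t], totals[attractors[t]], names[attractors[t]]),
        )
        if flows[best] <= 0:  # no flow anywhere: should not happen in a component
            best = 0
        clusters.setdefault(find(attractors[best]), []).append(j)
    return sorted(clusters.values(), key=lambda c: min(names[i] for i in c))


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[GeneFamily]:
    """Markov clustering of the similarity graph into gene families.

    Every gene lands in exactly one family; isolated genes form singleton
    families.  Clustering is run independently per connected component
    (Markov clustering never merges components).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    idx = {g: i for i, g in enumerate(graph.genes)}
    n = len(graph.genes)
    # connected components by union-find over edges
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in graph.edges:
        a, b = sorted(e)
        parent[find(idx[a])] = find(idx[b])
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    clusters: list[list[str]] = []
    for comp in comps.values():
        if len(comp) == 1:
            clusters.append([graph.genes[comp[0]]])
            continue
        names = [graph.genes[i] for i in comp]
        sub = {g: t for t, g in enumerate(names)}
        adj = np.zeros((len(comp), len(comp)))
        for e, w in graph.edges.items():
            a, b = sorted(e)
            if a in sub:
                adj[sub[a], sub[b]] = adj[sub[b], sub[a]] = w
        m = _mcl_matrix(adj, inflation, max_iter, tol)
        totals = adj.sum(axis=1)
        for cl in _clusters_from_limit(m, totals, names):
            clusters.append(sorted(names[i] for i in cl))

    clusters.sort(key=lambda c: c[0])
    width = max(5, len(str(len(clusters))))
    families = []
    for i, cl in enumerate(clusters):
        members: dict[str, list[str]] = {}
        for g in cl:
            members.setdefault(graph.genome_of[g], []).append(g)
        families.append(
            GeneFamily(f"F{i:0{width}d}", {g: sorted(v) for g, v in members.items()})
        )
    return families
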