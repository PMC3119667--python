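"""Minimum-flip labeling of trees of ortholog groups (TOGs).

A family that was partitioned into K SOGs yields K TOGs on the shared
species tree: binary leaf labels record which genomes contribute a gene.
Internal nodes (ancestral genomes) are labeled 1/0 for inferred
presence/absence so that the total number of *flips* — edges whose
endpoints carry different labels, i.e. gene births, duplications and
losses — is minimal, subject to two biological constraints:

* **intratree** (orthology is shaped by speciation only): within a TOG a
  node labeled 0 that has a 1-labeled ancestor may not have any 1-labeled
  descendant — a lost gene is never regained;
* **intertree** (a gene family is born only once): the nodes labeled 1 in
  at least one TOG of the family must form a connected region of the
  species tree.

Three interchangeable solvers are provided: an exhaustive oracle for small
instances, a node-centric dynamic program over per-node label vectors, and
a tree-centric dynamic program over union labelings, processed one TOG at
a time.  All three return the same optimal flip count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import SpeciesTree

__all__ = [
    "LabelingProblem",
    "LabelingSolution",
    "count_flips",
    "check_intratree",
    "check_intertree",
    "label_exhaustive",
    "label_node_centric",
    "label_tree_centric",
    "solve",
]


@dataclass
class LabelingProblem:
    """K TOGs on one species tree with fixed binary leaf labels.

    ``leaf_labels`` has shape (K, n_nodes); only leaf positions are read.
    Every TOG must have at least one 1-labeled leaf (an all-absent SOG
    cannot arise in the pipeline and is rejected defensively).
    """

    tree: SpeciesTree
    leaf_labels: np.ndarray

    def __post_init__(self):
        self.leaf_labels = np.asarray(self.leaf_labels, dtype=np.int8)
        if self.leaf_labels.ndim != 2 or self.leaf_labels.shape[1] != self.tree.n_nodes:
            raise ValueError("leaf_labels must have shape (K, n_nodes)")
        if self.leaf_labels.shape[0] < 1:
            raise ValueError("need at least one TOG")
        leaves = self.tree.leaves()
        if not np.all(self.leaf_labels[:, leaves].any(axis=1)):
            raise ValueError("every TOG must have at least one present (1) leaf")

    @property
    def k(self) -> int:
        return self.leaf_labels.shape[0]

    @classmethod
    def from_genome_labels(cls, tree: SpeciesTree, togs: list[dict[str, int]]) -> "LabelingProblem":
        """Build from per-TOG {genome: 0/1} maps (absent genomes default 0)."""
        labels = np.zeros((len(togs), tree.n_nodes), dtype=np.int8)
        for i, tog in enumerate(togs):
            for genome, lab in tog.items():
                labels[i, tree.leaf_of[genome]] = lab
        return cls(tree, labels)


@dataclass
class LabelingSolution:
    """Full binary labels (K, n_nodes) for all TOGs plus the minimum flip count."""

    labels: np.ndarray
    total_flips: int


# ---------------------------------------------------------------------------
# flip counting and constraint checks


def count_flips(labels: np.ndarray, tree: SpeciesTree) -> int:
    """Number of bicolored (01/10) edges of one fully labeled TOG."""
    labels = np.asarray(labels)
    if labels.shape != (tree.n_nodes,):
        raise ValueError("labels must cover every node of the tree")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("unlabeled or non-binary node label")
    nonroot = np.arange(tree.n_nodes) != tree.root
    return int(np.sum(labels[nonroot] != labels[tree.parent[nonroot]]))


def _strict_anc_desc_one(labels: np.ndarray, tree: SpeciesTree) -> tuple[np.ndarray, np.ndarray]:
    """Per node: has a 1 among strict ancestors / strict descendants."""
    sub = np.zeros(tree.n_nodes, dtype=bool)  # any 1 in subtree incl. self
    desc = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.postorder():
        c = tree.children[v]
        if c is not None:
            desc[v] = sub[c[0]] | sub[c[1]]
        sub[v] = bool(labels[v]) | desc[v]
    anc = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.preorder():
        c = tree.children[v]
        if c is not None:
            val = anc[v] | bool(labels[v])
            anc[c[0]] = val
            anc[c[1]] = val
    return anc, desc


def check_intratree(labels: np.ndarray, tree: SpeciesTree) -> bool:
    """True iff no node labeled 0 under a 1-labeled ancestor has a 1 below it."""
    labels = np.asarray(labels)
    anc, desc = _strict_anc_desc_one(labels, tree)
    return not np.any((labels == 0) & anc & desc)


def check_intertree(all_labels: np.ndarray, tree: SpeciesTree) -> bool:
    """True iff the union 1-set over all TOGs induces a connected subtree.

    In a tree the path between two nodes is unique, so pathwise 1-coverage
    is equivalent to connectivity of the union 1-set, which holds iff the
    union has exactly one topmost 1-node (a 1-node whose parent is 0, or
    the root).
    """
    union = np.asarray(all_labels).any(axis=0)
    if not union.any():
        return True
    tops = 0
    for v in range(tree.n_nodes):
        if union[v] and (v == tree.root or not union[tree.parent[v]]):
            tops += 1
    return tops == 1


# ---------------------------------------------------------------------------
# exhaustive oracle


def label_exhaustive(
    problem: LabelingProblem, enforce_intertree: bool = True, max_bits: int = 24
) -> LabelingSolution:
    """Globally minimal labeling by enumerating all internal labelings.

    Enumerates ``2^(K*(N-1))`` joint labelings (vectorized, in chunks), so a
    size guard rejects instances with more than ``max_bits`` free bits.
    The first optimum in a fixed enumeration order (root labels first, 0
    before 1) is returned, making the result deterministic.
    """
    tree, K = problem.tree, problem.k
    internal = [v for v in tree.postorder() if not tree.is_leaf(v)]
    nbits = K * len(internal)
    if nbits > max_bits:
        raise ValueError(f"exhaustive guard exceeded: {nbits} bits > {max_bits}")
    leaves = tree.leaves()
    parent, root = tree.parent, tree.root

    # bit layout: (root .. first internal) x TOG, root bits most significant,
    # so ascending candidate order prefers label 0 at the root.
    bit_of = {}
    b = nbits - 1
    for v in sorted(internal, reverse=True):
        for k in range(K):
            bit_of[(k, v)] = b
            b -= 1

    total = 1 << nbits
    chunk = 1 << 18
    best_flips, best_cand = None, None
    for start in range(0, total, chunk):
        cand = np.arange(start, min(start + chunk, total), dtype=np.int64)
        C = cand.shape[0]
        L = np.zeros((C, K, tree.n_nodes), dtype=bool)
        for k in range(K):
            for v in leaves:
                L[:, k, v] = bool(problem.leaf_labels[k, v])
            for v in internal:
                L[:, k, v] = (cand >> bit_of[(k, v)]) & 1
        # flips
        nonroot = [v for v in range(tree.n_nodes) if v != root]
        flips = np.zeros(C, dtype=np.int64)
        for v in nonroot:
            flips += np.sum(L[:, :, v] != L[:, :, parent[v]], axis=1)
        # intratree per TOG
        ok = np.ones(C, dtype=bool)
        sub = np.zeros((C, K, tree.n_nodes), dtype=bool)
        desc = np.zeros((C, K, tree.n_nodes), dtype=bool)
        for v in tree.postorder():
            c = tree.children[v]
            if c is not None:
                desc[:, :, v] = sub[:, :, c[0]] | sub[:, :, c[1]]
            sub[:, :, v] = L[:, :, v] | desc[:, :, v]
        anc = np.zeros((C, K, tree.n_nodes), dtype=bool)
        for v in tree.preorder():
            c = tree.children[v]
            if c is not None:
                val = anc[:, :, v] | L[:, :, v]
                anc[:, :, c[0]] = val
                anc[:, :, c[1]] = val
        viol = ((~L) & anc & desc).any(axis=(1, 2))
        ok &= ~viol
        if enforce_intertree:
            union = L.any(axis=1)  # (C, n_nodes)
            tops = np.zeros(C, dtype=np.int64)
            for v in range(tree.n_nodes):
                if v == root:
                    tops += union[:, v]
                else:
                    tops += union[:, v] & ~union[:, parent[v]]
            ok &= tops == 1
        flips = np.where(ok, flips, np.iinfo(np.int64).max)
        i = int(np.argmin(flips))
        if flips[i] != np.iinfo(np.int64).max and (best_flips is None or flips[i] < best_flips):
            best_flips, best_cand = int(flips[i]), int(cand[i])
    if best_flips is None:
        raise ValueError("no feasible labeling (cannot occur when every TOG has a 1-leaf)")
    labels = problem.leaf_labels.astype(np.int8).copy()
    for k in range(K):
        for v in internal:
            labels[k, v] = (best_cand >> bit_of[(k, v)]) & 1
    return LabelingSolution(labels, best_flips)


# ---------------------------------------------------------------------------
# node-centric dynamic program

# extended per-TOG labels
_Z, _P, _O = 0, 1, 2  # 0 (all descendants 0), 0-pending (0 here, 1 below), 1


def _vectors(K: int) -> list[tuple[int, ...]]:
    return list(itertools.product((_Z, _P, _O), repeat=K))


def _edge_compatible(vp: tuple[int, ...], vc: tuple[int, ...]) -> bool:
    """Per-TOG parent/child label rules plus the cross-TOG connectivity rule
    that a 1-carrying parent may not have a 'closed' child (pending but no 1)."""
    for pk, ck in zip(vp, vc):
        if pk == _Z and ck != _Z:
            return False
        if pk == _O and ck == _P:
            return False
    if any(pk == _O for pk in vp):
        if any(ck == _P for ck in vc) and not any(ck == _O for ck in vc):
            return False  # child subtree holds union-1 nodes detached from parent
    return True


def label_node_centric(problem: LabelingProblem) -> LabelingSolution:
    """Label all TOGs simultaneously by DP over per-node label vectors.

    Each species-tree node carries a vector in {0, 0-pending, 1}^K.  The
    0-pending label marks a node labeled 0 whose subtree contains a 1 in
    that TOG; it drives both the intratree rules (nothing below a 1 may be
    pending) and the connectivity rules of the intertree constraint, which
    thereby become local to each parent-children triple.
    """
    tree, K = problem.tree, problem.k
    vecs = _vectors(K)
    nvec = len(vecs)
    INF = float("inf")
    has_one = [any(x == _O for x in v) for v in vecs]
    pend_mask = [sum(1 << k for k, x in enumerate(v) if x != _Z) for v in vecs]
    nonzero = [m != 0 for m in pend_mask]
    cover_mask = [sum(1 << k for k, x in enumerate(v) if x in (_P, _O)) for v in vecs]

    # per-(parent vec, child vec): edge flips if compatible else None
    compat: list[list[int | None]] = [[None] * nvec for _ in range(nvec)]
    for i, vp in enumerate(vecs):
        for j, vc in enumerate(vecs):
            if _edge_compatible(vp, vc):
                compat[i][j] = sum((pk == _O) != (ck == _O) for pk, ck in zip(vp, vc))

    cost = [[INF] * nvec for _ in range(tree.n_nodes)]
    choice: list[dict[int, tuple[int, int]]] = [dict() for _ in range(tree.n_nodes)]

    for v in tree.postorder():
        c = tree.children[v]
        if c is None:
            fixed = tuple(_O if problem.leaf_labels[k, v] else _Z for k in range(K))
            cost[v][vecs.index(fixed)] = 0.0
            continue
        lo, hi = c
        for i, vp in enumerate(vecs):
            need = sum(1 << k for k, x in enumerate(vp) if x == _P)
            # reduce each child's feasible vectors to (cover-mask, nonzero) classes
            classes: list[dict[tuple[int, bool], tuple[float, int]]] = []
            for ch in (lo, hi):
                cls: dict[tuple[int, bool], tuple[float, int]] = {}
                for j in range(nvec):
                    f = compat[i][j]
                    if f is None or cost[ch][j] == INF:
                        continue
                    key = (cover_mask[j], nonzero[j])
                    val = cost[ch][j] + f
                    if key not in cls or val < cls[key][0]:
                        cls[key] = (val, j)
                classes.append(cls)
            best, arg = INF, None
            for (m1, nz1), (c1, j1) in classes[0].items():
                for (m2, nz2), (c2, j2) in classes[1].items():
                    if (need & ~(m1 | m2)) != 0:
                        continue  # a pending TOG must see a 1 below one child
                    if not has_one[i] and nz1 and nz2:
                        continue  # union-1 nodes under both children of a 0-node
                    if c1 + c2 < best:
                        best, arg = c1 + c2, (j1, j2)
            if arg is not None:
                cost[v][i] = best
                choice[v][i] = arg

    root = tree.root
    best_i, best_cost = None, INF
    order = sorted(range(nvec), key=lambda i: (tuple(int(x == _O) for x in vecs[i]), vecs[i]))
    for i in order:
        if cost[root][i] < best_cost:
            best_cost, best_i = cost[root][i], i
    if best_i is None:
        raise ValueError("no feasible labeling (cannot occur when every TOG has a 1-leaf)")

    labels = np.zeros((K, tree.n_nodes), dtype=np.int8)

    def backtrace(v: int, i: int):
        for k in range(K):
            labels[k, v] = 1 if vecs[i][k] == _O else 0
        if tree.children[v] is not None:
            j1, j2 = choice[v][i]
            backtrace(tree.children[v][0], j1)
            backtrace(tree.children[v][1], j2)

    backtrace(root, best_i)
    return LabelingSolution(labels, int(best_cost))


# ---------------------------------------------------------------------------
# tree-centric dynamic program


def _intratree_labelings(problem: LabelingProblem, k: int) -> list[tuple[int, int]]:
    """All intratree-feasible full labelings of TOG k as (node-bitmask, flips),
    in a deterministic order (root label 0 first)."""
    tree = problem.tree
    internal = sorted([v for v in tree.postorder() if not tree.is_leaf(v)], reverse=True)
    leaves = tree.leaves()
    out = []
    labels = np.zeros(tree.n_nodes, dtype=np.int8)
    for v in leaves:
        labels[v] = problem.leaf_labels[k, v]
    for bits in range(1 << len(internal)):
        for pos, v in enumerate(internal):  # internal[0]=root gets the MSB
            labels[v] = (bits >> (len(internal) - 1 - pos)) & 1
        if check_intratree(labels, tree):
            mask = int(sum(1 << v for v in range(tree.n_nodes) if labels[v]))
            out.append((mask, count_flips(labels, tree)))
    return out


def _mask_connected(mask: int, tree: SpeciesTree) -> bool:
    if mask == 0:
        return True
    tops = 0
    for v in range(tree.n_nodes):
        if (mask >> v) & 1 and (v == tree.root or not (mask >> tree.parent[v]) & 1):
            tops += 1
    return tops == 1


def label_tree_centric(problem: LabelingProblem, max_nodes: int = 20) -> LabelingSolution:
    """Label TOGs one at a time, tracking the running union TOG.

    State: the union (Boolean OR) of the binary labelings chosen for the
    TOGs processed so far, mapped to the best accumulated flip count.  The
    union state space is ``2^(2N-1)``, so a guard rejects trees with more
    than ``max_nodes`` nodes.  The answer is the cheapest final state whose
    union 1-set is connected (intertree constraint).
    """
    tree, K = problem.tree, problem.k
    if tree.n_nodes > max_nodes:
        raise ValueError(f"tree-centric guard exceeded: {tree.n_nodes} nodes > {max_nodes}")
    per_tog = [_intratree_labelings(problem, k) for k in range(K)]
    states: dict[int, int] = {0: 0}
    trace: list[dict[int, tuple[int, int]]] = []  # per TOG: new_union -> (labeling idx, prev union)
    for k in range(K):
        new_states: dict[int, int] = {}
        tr: dict[int, tuple[int, int]] = {}
        for u in sorted(states):
            base = states[u]
            for idx, (mask, flips) in enumerate(per_tog[k]):
                u2 = u | mask
                val = base + flips
                if u2 not in new_states or val < new_states[u2]:
                    new_states[u2] = val
                    tr[u2] = (idx, u)
        states = new_states
        trace.append(tr)
    final = [(cost, u) for u, cost in states.items() if _mask_connected(u, tree)]
    if not final:
        raise ValueError("no feasible labeling (cannot occur when every TOG has a 1-leaf)")
    best_cost, best_u = min(final)
    labels = np.zeros((K, tree.n_nodes), dtype=np.int8)
    u = best_u
    for k in range(K - 1, -1, -1):
        idx, prev = trace[k][u]
        mask = per_tog[k][idx][0]
        for v in range(tree.n_nodes):
            labels[k, v] = (mask >> v) & 1
        u = prev
    return LabelingSolution(labels, int(best_cost))


# ---------------------------------------------------------------------------
# strategy dispatch


def solve(problem: LabelingProblem, strategy: str = "auto") -> LabelingSolution:
    """Solve a labeling problem with the requested solver.

    ``auto`` uses the node-centric DP when the number of TOGs is small
    relative to the tree (K <= N: its 3^K vector space stays modest) and
    the tree-centric DP otherwise (its 2^(2N-1) union space is independent
    of K).  Both return the same optimal flip count.
    """
    if strategy == "exhaustive":
        return label_exhaustive(problem)
    if strategy == "node":
        return label_node_centric(problem)
    if strategy == "tree":
        return label_tree_centric(problem)
    if strategy == "auto":
        if problem.k <= problem.tree.n_leaves or problem.tree.n_nodes > 20:
            return label_node_centric(problem)
        return label_tree_centric(problem)
    raise ValueError(f"unknown strategy: {strategy!r}")
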