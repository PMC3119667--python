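"""Ortholog-group extraction and event classification from labeled TOGs.

Once every TOG of a family carries a full binary labeling, the highest
1-labeled nodes (nodes labeled 1 whose parent is labeled 0, or a 1-labeled
root) anchor the ortholog groups: all SOG genes at 1-labeled leaves under
an anchor form one group.  Groups with fewer than two genes are dropped —
they consist only of lineage-specific inparalogs or isolated genes.

Every flip edge is classified as exactly one event: a 1->0 edge is a gene
loss; a 0->1 edge is a gene birth if the parent node is labeled 0 in all
other TOGs of the family, otherwise a gene duplication (the gene already
existed in the ancestral genome, in another copy).  The root's origin is
not an event: events live on edges only.
"""

from __future__ import annotations

import numpy as np

from .labeling import LabelingSolution
from .model import EventRecord, OrthologGroup, SOG, SpeciesTree

__all__ = ["extract_groups", "classify_events"]


def extract_groups(
    labels: np.ndarray, tree: SpeciesTree, sog: SOG, tog_index: int = 0
) -> list[OrthologGroup]:
    """Ortholog groups of one fully labeled TOG.

    ``labels`` is the TOG's full binary labeling over the species tree.
    Group ids are deterministic: family id + TOG index + anchor node.
    """
    labels = np.asarray(labels)
    anchors = [
        v
        for v in range(tree.n_nodes)
        if labels[v] == 1 and (v == tree.root or labels[tree.parent[v]] == 0)
    ]
    groups = []
    for anchor in anchors:
        members: dict[str, str] = {}
        for leaf in tree.subtree_leaves(anchor):
            if labels[leaf] == 1:
                genome = tree.names[leaf]
                if genome in sog.genes:
                    members[genome] = sog.genes[genome]
        if len(members) >= 2:
            groups.append(
                OrthologGroup(
                    f"{sog.family_id}.{tog_index}.{anchor}", sog.family_id, tog_index, anchor, members
                )
            )
    return groups


def classify_events(
    solution: LabelingSolution, tree: SpeciesTree, family_id: str
) -> list[EventRecord]:
    """Per-edge event records for all jointly labeled TOGs of one family.

    The record count per TOG equals its flip count; kinds partition the
    flip edges.
    """
    labels = solution.labels
    K = labels.shape[0]
    events = []
    for k in range(K):
        for parent, child in tree.edges():
            p, c = int(labels[k, parent]), int(labels[k, child])
            if p == c:
                continue
            if p == 1:
                kind = "loss"
            else:
                others = [t for t in range(K) if t != k]
                if all(labels[t, parent] == 0 for t in others):
                    kind = "birth"
                else:
                    kind = "duplication"
            events.append(EventRecord(family_id, k, parent, child, kind))
    return events
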