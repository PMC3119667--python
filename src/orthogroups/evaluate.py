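"""Exact-match scoring of predicted ortholog groups and events.

A predicted group is a true positive only if its gene set equals a known
group exactly.  Sensitivity is TP / number of known groups; specificity
(elsewhere called precision) is TP / number of predicted groups.  Event
logs are compared as (species-tree branch, kind, family) multisets — the
finest granularity both sides share, since a predicted loss carries no
gene identity.
"""

from __future__ import annotations

from collections import Counter

__all__ = ["score_groups", "score_events", "map_predicted_families"]


def _as_sets(groups) -> list[frozenset]:
    out = []
    for g in groups:
        genes = g.values() if isinstance(g, dict) else g
        out.append(frozenset(genes))
    return out


def score_groups(predicted, truth) -> dict:
    """Exact-match TP count, sensitivity and specificity.

    ``predicted`` and ``truth`` are iterables of gene-id collections (sets
    or {genome: gene} maps).  Empty denominators are reported as None
    (undefined), never 0.  Predicted groups must be disjoint.
    """
    pred = _as_sets(predicted)
    tru = set(_as_sets(truth))
    seen: set = set()
    for p in pred:
        if seen & p:
            dup = sorted(seen & p)[0]
            raise ValueError(f"gene {dup} appears in two predicted groups")
        seen |= p
    tp = sum(1 for p in pred if p in tru)
    return {
        "tp": tp,
        "n_truth": len(tru),
        "n_predicted": len(pred),
        "sensitivity": tp / len(tru) if tru else None,
        "specificity": tp / len(pred) if pred else None,
    }


def score_events(predicted, truth) -> dict:
    """Per-kind sensitivity/specificity of (branch, kind, family) multisets."""
    pred = Counter(tuple(e) for e in predicted)
    tru = Counter(tuple(e) for e in truth)
    kinds = sorted({e[1] for e in pred} | {e[1] for e in tru})
    out = {}
    for kind in kinds:
        pk = Counter({e: c for e, c in pred.items() if e[1] == kind})
        tk = Counter({e: c for e, c in tru.items() if e[1] == kind})
        tp = sum((pk & tk).values())
        out[kind] = {
            "tp": tp,
            "n_truth": sum(tk.values()),
            "n_predicted": sum(pk.values()),
            "sensitivity": tp / sum(tk.values()) if tk else None,
            "specificity": tp / sum(pk.values()) if pk else None,
        }
    return out


def map_predicted_families(families, truth_family_of: dict[str, str]) -> dict[str, str]:
    """Map each predicted family id to the true family contributing most of
    its genes (ties: lexicographically smallest true family id)."""
    out = {}
    for fam in families:
        votes = Counter(
            truth_family_of[g] for g in fam.genes() if g in truth_family_of
        )
        if votes:
            out[fam.id] = min(votes, key=lambda f: (-votes[f], f))
    return out
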