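"""End-to-end orchestration: families -> pairwise -> SOGs -> labeling -> groups.

The stages exchange plain data objects; the CLI persists each stage to its
TSV artifact so an external pairwise ortholog assignment can replace the
built-in bidirectional-best-hit stand-in by file substitution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import map_predicted_families, score_events, score_groups
from .families import SimilarityGraph, mcl_cluster, score_all_pairs
from .groups import classify_events, extract_groups
from .labeling import LabelingProblem, LabelingSolution, solve
from .matching import build_multipartite, partition_family
from .model import EventRecord, GeneFamily, Genome, OrthologGroup, PairwiseOrthologSet, SOG, SpeciesTree
from .pairwise import bbh_orthologs
from .simulate import TruthRecord

__all__ = ["PipelineResult", "run_pipeline", "compute_pairwise_bbh", "evaluate_against_truth"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    families: list[GeneFamily]
    pairwise: PairwiseOrthologSet
    sogs: list[SOG]
    solutions: dict[str, LabelingSolution]  # family id -> joint labeling
    groups: list[OrthologGroup]
    events: list[EventRecord]
    sogs_by_family: dict[str, list[SOG]] = field(default_factory=dict)


def compute_pairwise_bbh(
    families: list[GeneFamily], graph: SimilarityGraph, genomes: list[Genome]
) -> PairwiseOrthologSet:
    """Bidirectional-best-hit one-to-one pairs for every genome pair, per family."""
    family_of = {g: f.id for f in families for g in f.genes()}
    by_id = {g.id: g for g in genomes}
    out = PairwiseOrthologSet()
    for ga, gb in itertools.combinations(sorted(by_id), 2):
        for fam in families:
            out.update(bbh_orthologs(fam, graph, by_id[ga], by_id[gb], family_of=family_of))
    return out


def run_pipeline(
    genomes: list[Genome],
    tree: SpeciesTree,
    *,
    graph: SimilarityGraph | None = None,
    families: list[GeneFamily] | None = None,
    pairwise: PairwiseOrthologSet | None = None,
    inflation: float = 2.0,
    min_score: float = 50.0,
    strategy: str = "auto",
) -> PipelineResult:
    """Run the full pipeline on genomes with sequences.

    Precomputed stage inputs (similarity graph, families, pairwise
    orthologs) can be injected; anything missing is computed.
    """
    if graph is None and (families is None or pairwise is None):
        graph = score_all_pairs(genomes, min_score=min_score)
    if families is None:
        families = mcl_cluster(graph, inflation=inflation)
    if pairwise is None:
        pairwise = compute_pairwise_bbh(families, graph, genomes)

    sogs: list[SOG] = []
    sogs_by_family: dict[str, list[SOG]] = {}
    solutions: dict[str, LabelingSolution] = {}
    groups: list[OrthologGroup] = []
    events: list[EventRecord] = []

    for fam in families:
        graph_f = build_multipartite(fam, pairwise, tree)
        fam_sogs = partition_family(graph_f, tree)
        sogs.extend(fam_sogs)
        sogs_by_family[fam.id] = fam_sogs
        problem = LabelingProblem.from_genome_labels(
            tree, [{g: 1 for g in s.genes} for s in fam_sogs]
        )
        sol = solve(problem, strategy=strategy)
        solutions[fam.id] = sol
        for i, s in enumerate(fam_sogs):
            groups.extend(extract_groups(sol.labels[i], tree, s, tog_index=i))
        events.extend(classify_events(sol, tree, fam.id))

    return PipelineResult(families, pairwise, sogs, solutions, groups, events, sogs_by_family)


def evaluate_against_truth(result: PipelineResult, truth: TruthRecord) -> dict:
    """Exact-match group metrics plus per-kind event metrics versus truth.

    Predicted events are projected to (branch, kind, true family) via a
    majority-vote family mapping; truth reversals are excluded (content
    events only).
    """
    metrics = {"groups": score_groups([g.genes for g in result.groups], truth.groups.values())}
    fam_map = map_predicted_families(result.families, truth.family_of)
    pred_events = [
        (e.child_node, e.kind, fam_map.get(e.family_id, "?")) for e in result.events
    ]
    true_events = [
        (branch, kind, family)
        for branch, kind, family, _lineage in truth.events
        if kind != "reversal"
    ]
    metrics["events"] = score_events(pred_events, true_events)
    return metrics
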