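# Methods

This note documents the models, algorithms and design choices behind
`orthogroups`, in the order the pipeline runs them, followed by the
simulator, the evaluation protocol, and known limitations.

## Similarity scoring and family construction

Families are meant to contain *all* homologs of a gene across the
compared genomes. The internal scorer assigns each gene pair a
bit-score-like similarity `2·L − 5·d`, where `d` is the global (NW) edit
distance computed with edlib and `L` the longer sequence length. The
score is symmetric, grows with alignment identity and length, and is
negative for unrelated random sequences, so any positive cutoff
(default `min_score = 50`) separates homologs from noise at moderate
divergence. A shared-k-mer prefilter (sparse gene × 12-mer presence
matrix product; pairs sharing fewer than 10 hashed 12-mers are skipped)
keeps the all-vs-all pass near-linear in practice. This prefilter is the
scorer's sensitivity envelope: pairs whose identity has decayed to the
point of sharing almost no 12-mers (roughly < 65–70% identity over 3 kb)
are never aligned. Real analyses at higher divergence should supply an
external score table (`similarity.tsv`) instead.

Markov clustering is reimplemented directly: the symmetric weight matrix
gets self-loops equal to each gene's maximum incident weight, columns are
normalized, and expansion (matrix squaring) alternates with inflation
(elementwise power, default 2.0, then renormalization) until the matrix
changes by less than `tol = 1e-6` or 100 iterations (non-convergence
returns the current partition with a warning). Clusters are read off the
attractor structure; a gene attracted to two clusters joins the one
receiving most of its flow, with ties broken by total incident weight and
then gene id, so the output is deterministic. Clustering runs per
connected component, which Markov clustering never merges.

## Pairwise one-to-one orthologs (the BBH stand-in)

The pipeline's contract for this stage is a one-to-one ortholog pair set
per genome pair with similarity weights. Production use is expected to
supply these from a dedicated rearrangement-aware pairwise assigner (by
dropping its `orthologs.<A>_<B>.tsv` files in place); the built-in
stand-in exists so simulated, closed-loop runs need no external tool.

The stand-in takes mutual best hits within each family and then greedily
pairs the remaining genes by descending score. Ranking uses the bit
score plus two gene-order terms, because sequence alone cannot separate
a recent duplicate from its source copy — both are equidistant in
expectation from any ortholog in a third genome, and the score noise is
correlated across genomes (the source's own post-duplication mutations
shift all of its scores together):

* a **neighbourhood bonus** (+100 per shared flanking-gene family; up to
  four non-self-family neighbours per side) that demotes duplicates
  displaced to a foreign locus — the set is unordered, so it is robust
  to reversals except at segment boundaries;
* a **tandem-rank penalty** (−100 per same-family gene within three
  positions on the lower-coordinate side) that takes the first member of
  a tandem array as the ancestral copy, consistent with the simulator's
  convention of inserting tandem duplicates 3' of their source.

Both terms are scale-separated: far below the score gap between correct
and incorrect family members (~500+), above the mutation noise between
near-identical copies (~±100). A tiny position term and finally the gene
id break exact ties, making the output deterministic and symmetric under
swapping the genome arguments.

## Partition into SOGs

Maximum-weight perfect matching of an N-partite graph is NP-hard for
N ≥ 3, so the partition is heuristic: stages (one per genome, padded
with dummy vertices to the family's maximum paralog count `n_max`) are
merged two at a time with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`), in species-tree post-order, so
a stage always merges with a phylogenetically close one. The weight
between two merged tuples is the sum of pairwise weights of their
members; dummies and non-ortholog pairs weigh 0, which is neutral for
maximization. On families with at most one gene per genome the heuristic
is weight-exact; on random dense weights it recovers ~99% of the
brute-force 3-dimensional optimum on average (not exact in general).

One refinement beyond the plain merge: final tuples are split into
connected components of their internal positive-weight evidence graph
before becoming SOGs. Padding forces every gene into some tuple even
when no ortholog pair supports its membership, and asserting orthology
on zero evidence silently absorbs inparalogs whose true counterpart was
lost. Because only zero-weight gene pairs are severed, the split never
discards matched weight. In simulation this raises exact-match accuracy
with ideal pairwise input from ~0.95 to ~0.99.

## TOG labeling

Minimum-flip labeling under the intratree and intertree constraints is
the combinatorial core. The intertree constraint is operationalized as
*connectivity of the union 1-set*: in a tree the path between two nodes
is unique, so "every node on a path between presence nodes is present in
some TOG" is equivalent to "the union 1-set induces a connected
subtree", which is checked by counting topmost 1-nodes.

* **Exhaustive oracle** — enumerates all `2^(K(N−1))` internal
  labelings (vectorized, chunked; guarded at 24 free bits), applying
  both constraints literally. It anchors every other solver in tests.
* **Node-centric DP** — one post-order pass over the species tree with
  per-node label vectors in {0, 0-pending, 1}^K, where 0-pending marks a
  node labeled 0 whose subtree contains a 1 in that TOG. Within a TOG
  only three parent→child label combinations are legal (0→0; 1→{0,1};
  pending→anything, with at least one child pending-or-1), which
  enforces the intratree constraint; two cross-TOG rules enforce union
  connectivity locally: a node with a 1-component may not have a child
  carrying pending without 1 (its subtree's presence region would
  detach), and a node with no 1-component may have at most one child
  with a non-all-zero vector (its children's presence regions would be
  separated). Child states are reduced to (pending-cover, non-zero)
  classes before combination, keeping the per-node cost polynomial in
  the 3^K vector count.
* **Tree-centric DP** — processes TOGs sequentially, tracking the union
  of the chosen labelings as a bitmask state (guarded at 2N−1 ≤ 20
  nodes): for each intratree-feasible labeling of the next TOG and each
  reachable union, accumulate flips and OR the masks; finish by taking
  the cheapest connected union and backtracing.

All three return the same optimum; the suite verifies agreement plus the
two optimality lemmas any minimum-flip labeling satisfies (a node with
two 1-children is never 0; a 1-node with two 0-children can always be
flipped to 0 unless that breaks feasibility) on hundreds of random
instances. `solve(strategy="auto")` uses the node-centric DP when
K ≤ N (its 3^K vector space stays modest) and the tree-centric DP
otherwise (its state space is independent of K). Co-optimal labelings
exist; each solver returns one deterministic representative (root label
0 preferred, then a fixed enumeration order) rather than enumerating all
optima.

## Groups and events

Anchors are 1-labeled nodes with a 0-labeled parent (or the 1-labeled
root); the SOG genes at 1-labeled leaves below an anchor form a group,
and groups with fewer than two genes are dropped as lineage-specific
content. Group ids are `family.togIndex.anchorNode`, so output is stable.
Each flip edge yields exactly one event record — loss for 1→0; for 0→1,
birth if the parent is 0 in all other TOGs of the family, else
duplication — so per-family event counts always equal the optimal flip
count. The root's own origin is not an event (events live on edges).

## Genome-evolution simulator

The simulator generates the study conditions, not a tunable benchmark.
Defaults: 5 single-chromosome genomes on a uniformly random rooted
binary topology (sequential random edge attachment, including above the
root); a root genome of 100 genes × 3,000 nt drawn uniformly from sense
codons; per speciation branch, 20 events split 40% duplications (half
tandem, inserted immediately 3' of the source; half at a uniform random
position), 20% births (fresh random coding-like gene, fresh family),
20% losses (uniform deletion; on an empty genome a warned no-op), and
20% segment reversals (two uniform cut points; order and strands flip).
Substitution is Jukes–Cantor on nucleotides with expected 0.02
substitutions/site per branch, applied in M+1 equal epochs interleaved
with the M events so all genes tick to one molecular clock; the epoch
substitution probability is `3/4·(1 − e^(−4t/3))`. The substitution
model is pluggable; a codon model would change absolute similarities but
not the relative ordering the pipeline consumes.

Ground truth: every gene carries a lineage id; speciation copies it, a
duplication gives the *new copy* a fresh lineage (parent–daughter
asymmetry), a birth opens a fresh lineage and family. True ortholog
groups are the lineages with ≥ 2 leaf genes; the event log records
(branch, kind, family, lineage). Identical parameters and seed give
byte-identical output.

What the simulator does *not* emulate: multiple chromosomes (hence no
translocations, fusions or fissions), indels and alternative splicing,
rate variation across genes or sites, codon usage structure, and any
form of gene conversion. Passing tests therefore demonstrate
correctness of the combinatorial pipeline under a clean clock-like
model, not robustness to every feature of real genomes.

## Evaluation protocol and observed accuracy

A predicted group is a true positive only when its gene set equals a
known group exactly. Sensitivity is TP over known groups; specificity
(elsewhere "precision") is TP over predicted groups; empty denominators
are reported as undefined rather than 0. Events are compared as
(species-tree branch, kind, family) multisets, the finest granularity
both sides share, with predicted families mapped to true families by
majority gene vote.

At the default simulation conditions, ten-replicate means land at
roughly 0.82–0.86 for both group metrics (the acceptance script prints
the per-replicate values). The binding constraint is the pairwise
stage: with truth-derived one-to-one pairs the same pipeline scores
≈ 0.99/1.00, so essentially the entire shortfall is the BBH stand-in's
parent–daughter ambiguity — a recent duplicate and its source are
sequence-equidistant from every third-genome ortholog, and a copy left
at the ancestral locus after its source's loss is indistinguishable even
with gene-order signals. A rearrangement-aware pairwise assigner is the
intended remedy, which is exactly why that stage is pluggable.

## Numerical and degenerate-input choices

* Gene positions are 0-based ranks per chromosome; strands are ±1; input
  position gaps are collapsed to ranks.
* The species tree must be supplied rooted and binary; non-binary nodes
  and duplicate leaf names are rejected outright (no midpoint-rooting
  fallback), because both labeling DPs assume the rooted binary scaffold.
* All TSV writers fully sort rows, so equal inputs give byte-identical
  files.
* All-absent TOGs cannot arise from the pipeline and are rejected
  defensively; a family present in a single genome yields singleton
  SOGs and no groups.
* Solver guards (24 enumeration bits; 20 tree nodes) are engineering
  choices sized to the intended ≤ ~10-genome regime.
* Problem sizes in tests and the acceptance script (100-gene root
  genomes, 10 replicates, ≤ 7×7 brute-force assignments, 200-instance
  solver sweeps) were chosen so the full closed loop stays in the
  tens-of-seconds range while every oracle comparison remains exhaustive.
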