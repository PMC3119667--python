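import numpy as np
import pytest

from conftest import random_labeling_problem
from orthogroups.labeling import (
    LabelingProblem,
    check_intertree,
    check_intratree,
    count_flips,
    label_exhaustive,
    label_node_centric,
    label_tree_centric,
    solve,
)
from orthogroups.model import SpeciesTree


def _problem(tree, togs):
    return LabelingProblem.from_genome_labels(tree, togs)


class TestFlipCounting:
    def test_all_ones_has_no_flips(self, quartet_tree):
        assert count_flips(np.ones(7, dtype=int), quartet_tree) == 0

    def test_single_bicolored_edge(self, quartet_tree):
        # root + left subtree 1, right subtree 0: only the root-right edge flips
        labels = np.zeros(7, dtype=int)
        left = quartet_tree.children[quartet_tree.root][0]
        labels[quartet_tree.root] = 1
        labels[left] = 1
        for leaf in quartet_tree.subtree_leaves(left):
            labels[leaf] = 1
        assert count_flips(labels, quartet_tree) == 1

    def test_matches_edge_by_edge_recount(self, quartet_tree):
        rng = np.random.default_rng(8)
        for _ in range(20):
            labels = rng.integers(0, 2, size=7)
            brute = sum(
                labels[v] != labels[p] for p, v in quartet_tree.edges()
            )
            assert count_flips(labels, quartet_tree) == brute

    def test_unlabeled_node_rejected(self, quartet_tree):
        labels = np.full(7, -1)
        with pytest.raises(ValueError):
            count_flips(labels, quartet_tree)


class TestConstraints:
    def test_loss_then_regain_violates_intratree(self):
        tree = SpeciesTree.from_nested((("a", "b"), "c"))
        # root=1 -> internal=0 -> leaf a=1: a 0-node under a 1-ancestor with a 1 below
        labels = np.zeros(5, dtype=int)
        labels[tree.root] = 1
        labels[tree.leaf_of["a"]] = 1
        assert not check_intratree(labels, tree)

    def test_single_leaf_one_set_satisfies_both(self, quartet_tree):
        labels = np.zeros(7, dtype=int)
        labels[quartet_tree.leaf_of["a"]] = 1
        assert check_intratree(labels, quartet_tree)
        assert check_intertree(labels[None, :], quartet_tree)

    def test_uncovered_root_path_violates_intertree(self, quartet_tree):
        t = quartet_tree
        left, right = t.children[t.root]
        tog1 = np.zeros(7, dtype=int)
        tog1[[t.leaf_of["a"], left]] = 1
        tog2 = np.zeros(7, dtype=int)
        tog2[[t.leaf_of["d"], right]] = 1
        # the a..d path passes the root, which is 0 in both TOGs
        assert not check_intertree(np.stack([tog1, tog2]), t)
        assert check_intratree(tog1, t) and check_intratree(tog2, t)


class TestWorkedInstances:
    def test_all_present_needs_no_flips(self, quartet_tree):
        p = _problem(quartet_tree, [dict(a=1, b=1, c=1, d=1)])
        for solver in (label_exhaustive, label_node_centric, label_tree_centric):
            sol = solver(p)
            assert sol.total_flips == 0
            assert (sol.labels == 1).all()

    def test_left_cherry_present_costs_one_flip(self, quartet_tree):
        p = _problem(quartet_tree, [dict(a=1, b=1, c=0, d=0)])
        assert label_exhaustive(p).total_flips == 1
        assert label_node_centric(p).total_flips == 1
        assert label_tree_centric(p).total_flips == 1

    def test_opposite_singletons_pay_for_family_connectivity(self, quartet_tree):
        # TOG1 has only leaf a, TOG2 only leaf d: a single birth point forces
        # the union to cover the a..d path, doubling the unconstrained cost.
        p = _problem(quartet_tree, [dict(a=1), dict(d=1)])
        assert label_exhaustive(p, enforce_intertree=False).total_flips == 2
        assert label_exhaustive(p).total_flips == 4
        assert label_node_centric(p).total_flips == 4
        assert label_tree_centric(p).total_flips == 4

    def test_exhaustive_guard(self):
        tree = SpeciesTree.from_nested(
            (((("a", "b"), ("c", "d")), (("e", "f"), ("g", "h"))), (("i", "j"), ("k", "l")))
        )
        labels = np.zeros((4, tree.n_nodes), dtype=np.int8)
        labels[:, tree.leaves()] = 1
        with pytest.raises(ValueError, match="guard"):
            label_exhaustive(LabelingProblem(tree, labels))


def _assert_valid_optimum(problem, sol, optimum):
    tree = problem.tree
    assert sol.total_flips == optimum
    recount = sum(count_flips(sol.labels[k], tree) for k in range(problem.k))
    assert recount == sol.total_flips
    for k in range(problem.k):
        assert check_intratree(sol.labels[k], tree)
        assert (sol.labels[k, tree.leaves()] == problem.leaf_labels[k, tree.leaves()]).all()
    assert check_intertree(sol.labels, tree)
    # Lemma guarantees of any optimal labeling
    for k in range(problem.k):
        for v in range(tree.n_nodes):
            c = tree.children[v]
            if c is None:
                continue
            l, r = sol.labels[k, c[0]], sol.labels[k, c[1]]
            assert not (sol.labels[k, v] == 0 and l == 1 and r == 1)  # Lemma 1
            if sol.labels[k, v] == 1 and l == 0 and r == 0:
                # Lemma 2 normalization: flipping v to 0 must break feasibility
                trial = sol.labels.copy()
                trial[k, v] = 0
                assert not (
                    check_intertree(trial, tree) and check_intratree(trial[k], tree)
                )


class TestSolverEquivalence:
    def test_random_sweep_all_solvers_agree(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            p = random_labeling_problem(rng, int(rng.integers(3, 7)), int(rng.integers(1, 4)))
            opt = label_exhaustive(p).total_flips
            for solver in (label_exhaustive, label_node_centric, label_tree_centric):
                _assert_valid_optimum(p, solver(p), opt)

    def test_flip_bounds(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            p = random_labeling_problem(rng, int(rng.integers(3, 7)), int(rng.integers(1, 4)))
            tree = p.tree
            sol = label_node_centric(p)
            assert sol.total_flips <= p.k * (2 * tree.n_leaves - 2)
            mixed = sum(
                1
                for k in range(p.k)
                if 0 < p.leaf_labels[k, tree.leaves()].sum() < tree.n_leaves
            )
            assert sol.total_flips >= mixed

    def test_intertree_never_decreases_optimum(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = random_labeling_problem(rng, int(rng.integers(3, 6)), int(rng.integers(1, 4)))
            assert (
                label_exhaustive(p).total_flips
                >= label_exhaustive(p, enforce_intertree=False).total_flips
            )


class TestSolveDispatch:
    def test_auto_matches_explicit_strategies(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            p = random_labeling_problem(rng, 4, int(rng.integers(1, 4)))
            flips = {s: solve(p, strategy=s).total_flips for s in ("auto", "node", "tree", "exhaustive")}
            assert len(set(flips.values())) == 1

    def test_unknown_strategy_rejected(self, quartet_tree):
        p = _problem(quartet_tree, [dict(a=1)])
        with pytest.raises(ValueError, match="strategy"):
            solve(p, strategy="nope")

    def test_all_zero_tog_rejected(self, quartet_tree):
        with pytest.raises(ValueError, match="present"):
            _problem(quartet_tree, [dict(a=0, b=0, c=0, d=0)])
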