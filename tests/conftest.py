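import numpy as np
import pytest

from orthogroups.labeling import LabelingProblem
from orthogroups.model import SpeciesTree
from orthogroups.simulate import SimulationParams, evolve, random_species_tree


@pytest.fixture
def quartet_tree() -> SpeciesTree:
    """((a,b),(c,d)): the 4-leaf balanced tree used by worked examples."""
    return SpeciesTree.from_nested((("a", "b"), ("c", "d")))


def random_labeling_problem(rng: np.random.Generator, n_leaves: int, k: int) -> LabelingProblem:
    """Random species tree + uniform random leaf labels, >=1 one-leaf per TOG."""
    tree = random_species_tree(n_leaves, rng)
    leaves = tree.leaves()
    labels = np.zeros((k, tree.n_nodes), dtype=np.int8)
    for i in range(k):
        while True:
            draw = rng.integers(0, 2, size=len(leaves))
            if draw.any():
                break
        labels[i, leaves] = draw
    return LabelingProblem(tree, labels)


@pytest.fixture(scope="session")
def small_simulation():
    """A modest simulated data set shared by pipeline-level tests."""
    params = SimulationParams(
        n_species=4, events_per_branch=6, branch_length=0.01, root_genes=40, seed=7
    )
    genomes, truth = evolve(params)
    return params, genomes, truth
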