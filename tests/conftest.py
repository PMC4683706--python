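import numpy as np
import pytest

from codonscan.alignment import CodonAlignment
from codonscan.codon_model import STANDARD_CODE, CodonFrequencies
from codonscan.io_formats import PhyloTree, TreeNode, parse_newick
from codonscan.synthetic_data import DEFAULT_OMEGAS, DEFAULT_TREE_NEWICK, simulate_alignment


@pytest.fixture(scope="session")
def rodent_tree() -> PhyloTree:
    return parse_newick(DEFAULT_TREE_NEWICK)


@pytest.fixture(scope="session")
def uniform_freqs() -> CodonFrequencies:
    return CodonFrequencies.uniform()


@pytest.fixture(scope="session")
def small_gene(rodent_tree, uniform_freqs):
    """One 300-codon gene simulated under the default branch omegas."""
    aln, truth = simulate_alignment(
        rodent_tree, 2.5, DEFAULT_OMEGAS, uniform_freqs, 300, seed=42
    )
    return aln, truth


def random_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """A random rooted binary tree with random lengths and sparse marks."""
    nodes = [
        TreeNode(name=f"t{i}", length=float(rng.uniform(0.01, 2.0)),
                 mark=int(rng.random() < 0.2))
        for i in range(n_leaves)
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(
            TreeNode(length=float(rng.uniform(0.01, 2.0)), children=[a, b])
        )
    return PhyloTree(TreeNode(children=nodes))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_alignment(seqs: dict[str, str]) -> CodonAlignment:
    return CodonAlignment(seqs=dict(seqs))


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE
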