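import dendropy
import numpy as np
import pytest

from allophylo.pipeline import CladeAnalysis
from allophylo.simulate import SimulationScenario, simulate_clade


@pytest.fixture(scope="session")
def small_dataset():
    """One modest allotetraploid clade shared across read-only tests."""
    sc = SimulationScenario(n_chromosomes=2, genes_per_chromosome=120, seed=4)
    return simulate_clade(sc)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    return CladeAnalysis(small_dataset.annotations, small_dataset.cds)


@pytest.fixture(scope="session")
def plain_dataset():
    """No rearrangements: gene order strictly preserved (truth-label tests)."""
    sc = SimulationScenario(
        n_chromosomes=2,
        genes_per_chromosome=100,
        inversions_per_branch=0.0,
        tandem_dups_per_branch=0.0,
        seed=9,
    )
    return simulate_clade(sc)


@pytest.fixture(scope="session")
def plain_analysis(plain_dataset):
    return CladeAnalysis(plain_dataset.annotations, plain_dataset.cds)


def read_tree(newick: str, tns=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        taxon_namespace=tns,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
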