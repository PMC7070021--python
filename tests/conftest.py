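import numpy as np
import pytest

from firsurvey.containers import GenotypeMatrix
from firsurvey.synthetic import PopSimTruth, gen_population_genotypes


@pytest.fixture(scope="session")
def two_group_sim():
    """Two clearly separated groups (Fst 0.3) for recovery checks."""
    truth = PopSimTruth(
        n_groups=2,
        fst=0.3,
        group_sizes=(25, 25),
        n_loci=30,
        alleles_per_locus=5,
        seed=11,
    )
    return gen_population_genotypes(truth)


@pytest.fixture(scope="session")
def three_group_sim():
    """Three-group Balding-Nichols simulation at the study scale."""
    truth = PopSimTruth(
        n_groups=3,
        fst=0.2,
        group_sizes=(60, 60, 60),
        n_loci=40,
        alleles_per_locus=5,
        seed=123,
    )
    return gen_population_genotypes(truth)


@pytest.fixture
def tiny_genotypes():
    """2 individuals x 3 loci, hand-constructed."""
    calls = np.empty((2, 3, 2), dtype=object)
    calls[0] = [(100, 102), (200, 200), (None, None)]
    calls[1] = [(100, 100), (200, 202), (300, 302)]
    return GenotypeMatrix(["a", "b"], ["L1", "L2", "L3"], calls)
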