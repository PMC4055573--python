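import numpy as np
import pytest
from hypothesis import settings

from phylohmm import GtrParams, HmmModel, HmmParams, ParentalForest
from phylohmm.trees import COALESCENT, parse_newick
from phylohmm.pipeline import seven_state_model

settings.register_profile("suite", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def jc():
    return GtrParams.jukes_cantor()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def allele_map3():
    return {"a": "A", "b": "B", "c": "C"}


@pytest.fixture(scope="session")
def forest3(allele_map3):
    """Three species, one allele each, two parental trees (the simple
    case)."""
    return ParentalForest(
        [parse_newick("((A:1,B:1):1.0,C:2);", COALESCENT),
         parse_newick("((B:1,C:1):1.0,A:2);", COALESCENT)],
        allele_map3, {1})


@pytest.fixture(scope="session")
def allele_map4():
    return {"d1": "D", "d2": "D", "s1": "S", "s2": "S"}


@pytest.fixture(scope="session")
def forest4(allele_map4):
    """Two species, two alleles each (the empirical-scan shape)."""
    return ParentalForest(
        [parse_newick("(D:20,S:20);", COALESCENT),
         parse_newick("(D:0.25,S:0.25);", COALESCENT)],
        allele_map4, {1})


@pytest.fixture(scope="session")
def model3(forest3, jc):
    return HmmModel(forest3, jc, HmmParams(0.1, 0.2, 0.2))


@pytest.fixture(scope="session")
def model4(forest4, jc):
    return HmmModel(forest4, jc, HmmParams(0.05, 0.1, 0.2))


@pytest.fixture(scope="session")
def generator7():
    """A 7-state model with emission-distinguishable genealogy states."""
    return seven_state_model(gamma=0.05, s1=0.1, s2=0.3)
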