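import numpy as np
import pytest

from sitesieve.seqio import Alignment
from sitesieve.substmodel import SubstitutionModel
from sitesieve.trees import Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_nt_alignment():
    return Alignment(
        ["a", "b", "c", "d"],
        np.array(
            [
                list("ACGTACGTA"),
                list("ACGTACGTT"),
                list("ACGAACGTA"),
                list("AC-TACNTA"),
            ]
        ),
        {"g1": (1, 9)},
    )


@pytest.fixture
def quartet_tree():
    return Tree.from_newick("((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.05);")


@pytest.fixture
def jc():
    return SubstitutionModel.jc()


def random_gtr(rng, alpha=None):
    ex = rng.uniform(0.3, 3.0, 6)
    fr = rng.dirichlet(np.full(4, 5.0))
    return SubstitutionModel.gtr(ex, fr, alpha=alpha)


def random_alignment(rng, taxa, n_sites):
    mat = rng.choice(list("ACGT"), size=(len(taxa), n_sites))
    return Alignment(list(taxa), mat)
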