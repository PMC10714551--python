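import numpy as np
import pytest

from peripagen import coalescent as ce
from peripagen import synth
from peripagen.alignments import LocusAlignment, PopulationMap


@pytest.fixture(scope="session")
def t4():
    """The hand-enumerated 4x10 toy with an all-ancestral outgroup."""
    return synth.t4_alignment()


@pytest.fixture(scope="session")
def t4_popmap():
    return PopulationMap(dict(synth.T4_POPS))


@pytest.fixture(scope="session")
def four_gamete():
    return synth.four_gamete_alignment()


@pytest.fixture
def rng():
    return np.random.default_rng(20231212)


def random_binary_alignment(rng, n=6, L=30, p=0.3, locus_id="rand",
                            with_outgroup=True):
    """Random biallelic toy: ancestral A, derived T at Bernoulli sites."""
    mat = np.where(rng.random((n, L)) < p, "T", "A")
    seqs = [(f"s{i}", 0, "".join(mat[i])) for i in range(n)]
    og = ["A" * L] if with_outgroup else []
    return LocusAlignment(locus_id, seqs, outgroup=og)


@pytest.fixture(scope="session")
def panmictic():
    """Constant-size single-deme control, N = 1000."""
    return ce.single_deme_scenario(1000.0)
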