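import numpy as np
import pytest

from foulscan import synthetic as syn


@pytest.fixture(scope="session")
def coi_taxa():
    return syn.gen_reference_taxa(20, ("COI",), seed=11)


@pytest.fixture(scope="session")
def all_marker_taxa():
    return syn.gen_reference_taxa(8, syn.MARKERS, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
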