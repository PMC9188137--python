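import numpy as np
import pytest

from geoseed import MaskedSequence
from geoseed.synthetic import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_pair(rng):
    """A small pair of i.i.d. uniform sequences on two genome labels."""
    def make(len1=400, len2=400, id1="s1", id2="s2"):
        return (
            [MaskedSequence(id1, "g1", random_dna(rng, len1))],
            [MaskedSequence(id2, "g2", random_dna(rng, len2))],
        )
    return make
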