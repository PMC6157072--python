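import numpy as np
import pytest

import matekit as mk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_unrelated():
    """Four unrelated, non-inbred candidates with distinct criteria."""
    ids = list("ABCD")
    cand = mk.CandidateSet(ids, criterion=[1.0, 2.0, 3.0, 4.0])
    C = mk.CoancestryMatrix(ids, np.eye(4) * 0.5)
    return cand, C


@pytest.fixture
def sib_structure():
    """Two full sibs (kinship 0.25) plus two unrelated candidates."""
    ids = ["S1", "S2", "U1", "U2"]
    V = np.eye(4) * 0.5
    V[0, 1] = V[1, 0] = 0.25
    cand = mk.CandidateSet(ids, criterion=[4.0, 3.0, 2.0, 1.0])
    return cand, mk.CoancestryMatrix(ids, V)
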