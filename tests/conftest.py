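import numpy as np
import pytest

from randkit import designs as dz

SEED = 1234

#: the twelve head-to-head procedures at n = 50
def twelve_designs(n=50):
    return [
        dz.rand_rule(n),
        dz.tbd(n),
        dz.pbd(2),
        dz.pbd(4),
        dz.bsd(3),
        dz.bcdwit(2.0 / 3.0, 3),
        dz.bcd(2.0 / 3.0),
        dz.abcd(2.0),
        dz.gbcd(1.0),
        dz.gbcd(2.0),
        dz.gbcd(5.0),
        dz.crd(),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def worked_example():
    """The n = 8 rare-disease trial: observed sequence and binary responses."""
    delta = np.array([1 if c == "E" else 0 for c in "CEECECCE"], dtype=np.int8)
    y = np.array([1.0 if c == "S" else 0.0 for c in "FSSFFFFS"])
    return delta, y


#: all 25 possible 4-vs-4 outcomes with their published one-sided Fisher
#: exact p-values (keys: successes on experimental, successes on control)
FISHER_TABLE_4V4 = {
    (0, 0): 1.0, (1, 1): 0.7857, (2, 2): 0.7571, (3, 3): 0.7857, (4, 4): 1.0,
    (1, 0): 0.5, (2, 0): 0.2143, (3, 0): 0.0714, (4, 0): 0.0143,
    (0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0, (0, 4): 1.0,
    (2, 1): 0.5, (3, 1): 0.2429, (4, 1): 0.0714,
    (1, 2): 0.9286, (1, 3): 0.9857, (1, 4): 1.0,
    (3, 2): 0.5, (4, 2): 0.2143,
    (2, 3): 0.9286, (2, 4): 1.0,
    (4, 3): 0.5, (3, 4): 1.0,
}
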