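import numpy as np
import pytest

from cxnav.arena_world import make_arena
from cxnav.cx_model import DynamicsConfig, Phenotype
from cxnav.sensory_encoding import Condition


@pytest.fixture(scope="session")
def open_arena():
    return make_arena("open")


@pytest.fixture(scope="session")
def simple_maze():
    return make_arena("simple_maze")


@pytest.fixture(scope="session")
def complex_maze():
    return make_arena("complex_maze")


@pytest.fixture(scope="session")
def cfg():
    return DynamicsConfig()


def handcrafted_weights() -> np.ndarray:
    """A wiring that solves the open arena from the start region.

    Forward is driven by landmark 1 in the agent's own sector (start) or by
    heading North; turn-left is driven by heading East but vetoed while
    landmark 1 is still in the own sector.  Net effect: run east out of
    sector 1, turn left once in sector column 2, run north into target 1.
    """
    W = np.zeros((14, 32))
    # input rows: body N=0, E=1; visual landmark 1 = 4
    for l in range(3):
        W[0, 0 + l] = 1.0   # body N -> EB wedge 0 (forward)
        W[4, 0 + l] = 1.0   # landmark-1-in-sector -> EB wedge 0
        W[1, 3 + l] = 1.0   # body E -> EB wedge 1 (turn left)
        W[4, 3 + l] = -1.0  # landmark 1 vetoes the turn while in sector 1
    W[0, 24] = 1.0
    W[4, 24] = 1.0          # LAL module 0 (forward)
    W[1, 25] = 1.0
    W[4, 25] = -1.0         # LAL module 1 (turn left)
    return W


@pytest.fixture(scope="session")
def handcrafted_phenotype():
    return Phenotype(condition=Condition.COMBINED, weights=handcrafted_weights(),
                     seed="handcrafted")
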