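import numpy as np
import pytest

from synaptrend.cable import discretise
from synaptrend.morphology import Morphology
from synaptrend.synthetic import generate_morphology


@pytest.fixture(scope="session")
def default_comps():
    """Discretised default synthetic cell (shared: discretisation is pure)."""
    return discretise(generate_morphology(), 10.0)


@pytest.fixture(scope="session")
def small_comps():
    """A small cell for fast simulation tests."""
    m = generate_morphology(n_obliques=6, oblique_spacing=50.0,
                            n_basal=2, basal_length=100.0)
    return discretise(m, 10.0)


def cylinder_morphology(length_um: float = 100.0, radius_um: float = 0.5,
                        node_um: float = 50.0) -> Morphology:
    """Unbranched non-soma cylinder along +y (cable-theory test geometry)."""
    n = int(round(length_um / node_um)) + 1
    xyz = np.zeros((n, 3))
    xyz[:, 1] = np.arange(n) * node_um
    return Morphology(xyz=xyz, radius=np.full(n, radius_um),
                      parent=np.arange(n) - 1, ntype=np.full(n, 4))
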