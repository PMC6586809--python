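import numpy as np
import pytest

from coroflow.vasctree import (GantryGeometry, GantryView, TreeParams,
                               VesselSegment, VesselTree, generate_tree)


def straight_tube_tree(radius=1.5, length=20.0, n=21, axis=2):
    pts = np.zeros((n, 3))
    pts[:, axis] = np.linspace(0.0, length, n)
    seg = VesselSegment(0, "tube", pts, np.full(n, radius))
    return VesselTree([seg], 0)


@pytest.fixture(scope="session")
def tube_tree():
    return straight_tube_tree()


@pytest.fixture(scope="session")
def left_tree():
    """A small left coronary tree used across geometry tests."""
    params = TreeParams(scale=0.4, n_diagonals=2, n_marginals=1)
    return generate_tree("left", params, seed=11)


@pytest.fixture(scope="session")
def gantry():
    return GantryGeometry(GantryView(-30.0, 20.0), GantryView(40.0, -15.0))
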