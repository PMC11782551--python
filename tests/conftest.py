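import numpy as np
import pytest

from angioimr.vessel_tree import VesselSegment, VesselTree
from angioimr.synthetic_data import (
    PhantomConfig,
    default_boundary_conditions,
    generate_phantom_tree,
)


@pytest.fixture
def chain_tree():
    """Three-segment chain: root -> a -> b -> c, tapering 4 -> 2.5 mm."""
    return VesselTree(
        segments=[
            VesselSegment("s1", "root", "a", 20.0, 4.0, 3.5),
            VesselSegment("s2", "a", "b", 20.0, 3.5, 3.0),
            VesselSegment("s3", "b", "c", 20.0, 3.0, 2.5),
        ],
        inlet_node="root",
    )


@pytest.fixture
def y_tree():
    """Trunk with a symmetric bifurcation into two equal daughters."""
    return VesselTree(
        segments=[
            VesselSegment("trunk", "root", "j", 25.0, 3.5, 3.0),
            VesselSegment("left", "j", "L", 20.0, 3.0, 2.5),
            VesselSegment("right", "j", "R", 20.0, 3.0, 2.5),
        ],
        inlet_node="root",
        branch_labels={"L": "LAD", "R": "LCX"},
    )


@pytest.fixture
def phantom():
    return generate_phantom_tree(PhantomConfig(seed=1, depth=3))


@pytest.fixture
def phantom_bc(phantom):
    return default_boundary_conditions(phantom)


def random_tree(rng: np.random.Generator) -> VesselTree:
    """Random valid rooted tree with 1-20 segments and coronary-ish geometry."""
    from angioimr.synthetic_data import generate_random_tree

    return generate_random_tree(rng)
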