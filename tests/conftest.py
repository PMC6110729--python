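import numpy as np
import pytest

from axonfield.cable import FiberGeometry, MembraneParams, SolverConfig


@pytest.fixture
def node_geometry() -> FiberGeometry:
    """Node-of-Ranvier segment: 1.08 µm long, no myelin."""
    return FiberGeometry(radius=5.0, segment_length=1.08, segment_type="node")


@pytest.fixture
def myelinated_geometry() -> FiberGeometry:
    return FiberGeometry(radius=5.0, segment_length=3.08,
                         segment_type="myelinated", myelin_thickness=3.63)


@pytest.fixture
def membrane() -> MembraneParams:
    return MembraneParams()


@pytest.fixture
def quiet_solver() -> SolverConfig:
    """Short unstimulated run for rest/stability checks."""
    return SolverConfig(dt=0.005, dx=1.0, n_segments=10, n_steps=50,
                        coupling="k-rule")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
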