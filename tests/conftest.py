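import numpy as np
import pytest

from reachmap.extraction import Loop, ResampledLoop, canonicalize, resample_loop
from reachmap.simulate import KinematicChain, SubjectSpec


@pytest.fixture
def unit_square() -> Loop:
    return Loop(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def noiseless_subject() -> SubjectSpec:
    return SubjectSpec("S00", KinematicChain(), noise_sd=0.0, seed=7)


def circle_loop(radius: float, n: int = 100, center=(0.0, 0.0)) -> ResampledLoop:
    """Canonical n-point loop on a circle (exactly arc-uniform)."""
    t = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )
    return resample_loop(canonicalize(Loop(pts)), n)


@pytest.fixture
def circle_factory():
    return circle_loop
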