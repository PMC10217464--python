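import numpy as np
import pytest

from striatome.core import ROIMask, Volume3D
from striatome.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default noisy phantom with its ground-truth masks."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def noisefree_phantom():
    spec = PhantomSpec(noise_scale=0.0, seed=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_roi():
    """A small irregular ROI in a random volume, for feature tests."""
    rng = np.random.default_rng(42)
    data = rng.integers(0, 20, size=(6, 7, 5)).astype(float)
    mask = np.zeros((6, 7, 5), bool)
    mask[1:5, 2:6, 1:4] = True
    mask[2, 3, 2] = False  # a hole
    return Volume3D(data, (1.0, 1.0, 1.0)), ROIMask(mask, (1.0, 1.0, 1.0))


def tiny_texture_cases():
    """Integer test arrays (<= 4x4x2) with masks, for matrix oracles."""
    rng = np.random.default_rng(7)
    cases = []
    # full-mask random arrays
    for shape in [(4, 4, 2), (3, 4, 2), (4, 3, 1)]:
        arr = rng.integers(1, 5, size=shape)
        cases.append((arr, np.ones(shape, bool)))
    # irregular mask
    arr = rng.integers(1, 4, size=(4, 4, 2))
    mask = rng.random((4, 4, 2)) > 0.3
    mask[0, 0, 0] = True  # guarantee non-empty
    cases.append((arr, mask))
    # constant array (degenerate single level)
    cases.append((np.ones((3, 3, 2), int), np.ones((3, 3, 2), bool)))
    # two-level stripes
    arr = np.tile(np.array([[1, 2], [1, 2]]), (2, 2, 1)).reshape(4, 4, 1)
    cases.append((arr, np.ones((4, 4, 1), bool)))
    return cases
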