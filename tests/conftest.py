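import numpy as np
import pytest

from sockeica.imaging_io import EventTrain, Mask3D, Volume4D
from sockeica.phantom import PhantomSpec, generate_phantom

SMALL_GRID = (24, 24, 12)
FOUR_ARTIFACTS = ("edge_ring", "csf_pulsation", "high_freq_machine", "spotty")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, artifact-free phantom: deconvolution should be exact."""
    spec = PhantomSpec(
        grid=SMALL_GRID, n_volumes=200, seed=11, artifact_sources=(), noise_sd=0.0
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """All five artifact families plus smoothed white noise."""
    spec = PhantomSpec(grid=SMALL_GRID, n_volumes=200, seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def sock_phantom():
    """The four catchable artifact families + two neural sources."""
    spec = PhantomSpec(
        grid=SMALL_GRID, n_volumes=200, seed=5, artifact_sources=FOUR_ARTIFACTS
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cube_mask():
    data = np.zeros((13, 13, 13), dtype=bool)
    data[2:11, 2:11, 2:11] = True  # 9x9x9 solid cube
    return Mask3D(data, kind="brain")


def make_volume(data, tr=3.0):
    return Volume4D(np.asarray(data, dtype=float), tr=tr)
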