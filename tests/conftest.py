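import numpy as np
import pytest

from repliconscope import synth
from repliconscope.datatypes import VoxelStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def confocal_axial_scale():
    """Axial deflation factor making separations resolution-equivalent
    for the coarsest (confocal) rendering."""
    return synth.CONFOCAL.lateral_fwhm / synth.CONFOCAL.axial_fwhm


def make_blob_stack(centres, sigmas=(1.5, 2.0, 2.0), shape=(9, 32, 32),
                    amplitude=1.0, background=0.0):
    """Noise-free stack with Gaussian blobs at the given (z, y, x) centres."""
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]]
    data = np.full(shape, float(background))
    for c in centres:
        data += amplitude * np.exp(
            -0.5 * (
                ((z - c[0]) / sigmas[0]) ** 2
                + ((y - c[1]) / sigmas[1]) ** 2
                + ((x - c[2]) / sigmas[2]) ** 2
            )
        )
    return VoxelStack(data, 100.0, 300.0, "synthetic")


@pytest.fixture
def blob_stack_factory():
    return make_blob_stack
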