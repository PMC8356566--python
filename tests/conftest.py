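import numpy as np
import pytest

from octaslabs import (
    PhantomConfig,
    SegmentationParams,
    align_repeats,
    generate_phantom,
    mask_low_signal,
    segment_boundaries,
    smooth_boundaries,
    speckle_variance,
)
from octaslabs.geometry import AcquisitionGeometry, AcquisitionVolume

TERM_SEED = 7


@pytest.fixture(scope="session")
def term_phantom():
    """Default three-layer phantom with speckle, flow and a foveal pit."""
    return generate_phantom(PhantomConfig(seed=TERM_SEED))


@pytest.fixture(scope="session")
def term_flow(term_phantom):
    volume, _ = term_phantom
    aligned = align_repeats(volume, max_shift_px=3)
    flow = speckle_variance(aligned)
    return mask_low_signal(flow, aligned, floor=0.05)


@pytest.fixture(scope="session")
def term_bounds(term_phantom):
    volume, _ = term_phantom
    return smooth_boundaries(segment_boundaries(volume, SegmentationParams()), 5)


@pytest.fixture(scope="session")
def early_phantom():
    return generate_phantom(PhantomConfig(stage="early", seed=TERM_SEED))


def random_volume(rng, nr=3, nb=4, nz=12, nx=6) -> AcquisitionVolume:
    geometry = AcquisitionGeometry(n_repeats=nr, n_bscans=nb, n_ascans=nx)
    return AcquisitionVolume(geometry=geometry, intensities=rng.random((nr, nb, nz, nx)))
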