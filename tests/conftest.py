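import numpy as np
import pytest

from histostack.phantom import PhantomSpec, build_phantom_dataset


@pytest.fixture(scope="session")
def small_phantom():
    """Five-stain phantom at desk scale for unit tests (64x64x18)."""
    # distortion scaled with the grid (the default 10 px goes with the
    # 128-px desk scale)
    spec = PhantomSpec(
        seed=7, grid_shape=(64, 64, 18), vessel_count=3, vessel_radius_range=(2.0, 3.5),
        distortion_amplitude=6.0,
    )
    return build_phantom_dataset(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Undistorted, jitter-free phantom: sections already aligned."""
    spec = PhantomSpec(
        seed=11,
        grid_shape=(64, 64, 18),
        vessel_count=3,
        vessel_radius_range=(2.0, 3.5),
        distortion_amplitude=0.0,
        affine_jitter=(0.0, 0.0),
    )
    return build_phantom_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
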