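import numpy as np
import pytest

from gtvconcord import Grid, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact phantom used throughout: 40x48x48 voxels at 3x1x1 mm."""
    return PhantomSpec(
        grid_shape=(40, 48, 48),
        spacing=(3.0, 1.0, 1.0),
        tumor_location="middle",
        tumor_length=36.0,
        tumor_radius=8.0,
        wall_thickness=6.0,
        tumor_suvmax=10.0,
        suv_noise_sd=0.0,
        hu_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_patient(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def tiny_grid() -> Grid:
    return Grid((12, 14, 16), (2.0, 1.0, 1.5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
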