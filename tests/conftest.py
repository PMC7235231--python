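import numpy as np
import pytest

from pxct.phantom import DEFAULT_BEAM, QUARTZ, PhantomSpec
from pxct.volume import Volume3D


@pytest.fixture(scope="session")
def beam():
    return DEFAULT_BEAM


@pytest.fixture()
def small_matrix_spec():
    """A 32^3 clean quartz pillar in air (no PSF, no noise)."""
    return PhantomSpec(
        shape=(32, 32, 32),
        beam=DEFAULT_BEAM,
        matrix_material=QUARTZ,
        inclusions=[],
        psf_fwhm_voxels=0.0,
        noise_sigma_frac=0.0,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_volume(grid, channel="delta", voxel=28.53):
    return Volume3D(grid=grid, channel=channel, voxel_size_nm=voxel)
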