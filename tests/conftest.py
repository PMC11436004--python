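import numpy as np
import pytest

import mufield as mf


@pytest.fixture(scope="session")
def tiny_phantom():
    return mf.make_phantom("soft_adjacent", 32, 1.0, seed=11)


@pytest.fixture(scope="session")
def tiny_geometry(tiny_phantom):
    det_shape, det_spacing = mf.fit_detector(tiny_phantom, n_pixels=32)
    return mf.ConeBeamGeometry.circular(
        n_views=20,
        sad=500.0,
        sdd=1000.0,
        detector_shape=det_shape,
        detector_spacing=det_spacing,
    )


@pytest.fixture(scope="session")
def tiny_projections(tiny_phantom, tiny_geometry):
    return mf.render_drr(tiny_phantom, tiny_geometry, n_samples=64)


@pytest.fixture(scope="session")
def homogeneous_cube():
    """200 mm cube of constant mu = 0.01 / mm (chord through center = 200 mm)."""
    values = np.full((50, 50, 50), 0.01)
    return mf.VolumeGrid(values, spacing=(4.0, 4.0, 4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
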