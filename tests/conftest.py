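import numpy as np
import pytest

import fanpat as fp


@pytest.fixture(scope="session")
def arc384():
    return fp.build_array()


@pytest.fixture(scope="session")
def breast():
    return fp.derive_optics(0.2, 10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_instance():
    """8-element, 16^3-voxel, 64-sample instance whose window covers the grid."""
    geom = fp.build_array(8, 4.0, 12.0)
    plan = fp.AcquisitionPlan(
        n_angles=1, angular_step=1.8, sampling_rate=2e6, n_samples=64, sound_speed=1500
    )
    grid = fp.VoxelGrid(origin=(7.5, -0.4, 7.5), spacing=0.05, shape=(16, 16, 16))
    rng = np.random.default_rng(7)
    plane = fp.RFPlane(
        pose_angle=0.0, samples=rng.normal(size=(8, 64)), sampling_rate=2e6
    )
    return geom, plan, grid, plane
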