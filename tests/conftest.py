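import numpy as np
import pytest

import nucshuttle as ns

DEFAULT_VOXEL = (0.4, 0.2, 0.2)


@pytest.fixture(scope="session")
def default_scene():
    return ns.build_scene(target_nuclear_fraction=0.782, seed=1)


@pytest.fixture(scope="session")
def rendered_stack(default_scene):
    shape = ns.grid_for_scene(default_scene, DEFAULT_VOXEL)
    return ns.render(
        default_scene, ns.OpticsParams(), shape, DEFAULT_VOXEL, seed=101
    )


@pytest.fixture(scope="session")
def noiseless_stack(default_scene):
    shape = ns.grid_for_scene(default_scene, DEFAULT_VOXEL)
    optics = ns.OpticsParams(
        background_level=0.0, read_noise_sd=0.0, photon_scale=None
    )
    return ns.render(default_scene, optics, shape, DEFAULT_VOXEL, seed=None)


@pytest.fixture
def tiny_stack():
    rng = np.random.default_rng(7)
    data = rng.integers(0, 1000, size=(2, 8, 16, 16)).astype(np.uint16)
    return ns.VolumeStack(data, (0.5, 0.2, 0.2), ("nuclear", "reporter"))
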