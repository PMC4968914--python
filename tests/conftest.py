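import numpy as np
import pytest

import omagflux as og


@pytest.fixture(scope="session")
def noiseless_static():
    """Noiseless flat-layer phantom with no flow: the null case."""
    scene = og.flat_scene(shape=(16, 16, 64))
    cube, truth = og.generate_cube(scene)
    return scene, cube, truth


@pytest.fixture(scope="session")
def noiseless_vol(noiseless_static):
    _, cube, _ = noiseless_static
    return og.compute_flow(og.compensate_bulk_phase(cube))


@pytest.fixture(scope="session")
def capillary_phantom():
    """Noisy phantom with capillaries, used by detection-oriented tests."""
    scene = og.flat_scene(
        shape=(32, 32, 64), capillary_density=0.12, noise_sigma=0.05, seed=7
    )
    cube, truth = og.generate_cube(scene)
    vol = og.compute_flow(og.compensate_bulk_phase(cube))
    return scene, cube, truth, vol


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
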