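import numpy as np
import pytest

from fltquant import synth, tomo
from fltquant.gating import GateSequence


@pytest.fixture(scope="session")
def gates():
    return GateSequence()


@pytest.fixture(scope="session")
def coarse_tomo():
    """Coarse slab phantom + geometry + Jacobian shared by tomo tests."""
    cfg = synth.TomoConfig(voxel_size=2.0, lateral=(20.0, 20.0))
    phantom, geom = synth.generate_tomo_phantom(cfg, 1)
    jac = tomo.build_jacobian(phantom, geom)
    return cfg, phantom, geom, jac


@pytest.fixture(scope="session")
def coarse_traces(coarse_tomo, gates):
    _, phantom, geom, jac = coarse_tomo
    return synth.simulate_tomo_data(phantom, geom, gates, jacobian=jac)


@pytest.fixture(scope="session")
def bands_slide():
    cfg = synth.MicroscopyConfig(shape=(500, 500), layout="bands")
    return synth.generate_microscopy_slide(cfg, 7)


@pytest.fixture(scope="session")
def blocks_slide():
    cfg = synth.MicroscopyConfig(shape=(400, 400), layout="blocks")
    return synth.generate_microscopy_slide(cfg, 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
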