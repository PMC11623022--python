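import numpy as np
import pytest

from eegaad.montage import packaged_montage, project_montage
from eegaad.simulate import SimulationConfig, make_dataset


@pytest.fixture(scope="session")
def montage64():
    return packaged_montage(64)


@pytest.fixture(scope="session")
def projected64(montage64):
    return project_montage(montage64)


@pytest.fixture(scope="session")
def highsnr_maps():
    """Small, strongly separable two-class map collection (40 maps)."""
    cfg = SimulationConfig(duration_s=2.0, lateralization=3.0, snr=5.0)
    maps, manifest = make_dataset(20, cfg, seed=1234)
    return maps, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
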