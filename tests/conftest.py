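import numpy as np
import pytest

from dtialps import PhantomSpec, make_scheme, default_presets
from dtialps.phantom import GroupPreset


@pytest.fixture(scope="session")
def reduced_spec():
    return PhantomSpec.reduced(snr=20.0)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec.reduced(snr=np.inf)


@pytest.fixture(scope="session")
def protocol_scheme():
    """The 12-shell, 99-direction acquisition scheme."""
    return make_scheme(seed=0)


@pytest.fixture(scope="session")
def minimal_scheme():
    """Smallest valid tensor design: one b=0 plus six b=1000 directions."""
    return make_scheme([0, 1000], n_directions=6, seed=0)


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def hc_preset(presets):
    return presets[0]


@pytest.fixture
def isotropic_preset():
    """Every tissue compartment shares one isotropic tensor → true ALPS = 1."""
    d = 0.7e-3
    return GroupPreset(
        name="HC",
        alps_mean={"left": 1.0, "right": 1.0},
        alps_sd={"left": 0.0, "right": 0.0},
        denominator_diffusivity=d,
        fiber_diffusivity=d,
        hippo_ad_mean=d,
        hippo_ad_sd=0.0,
        hippo_rd_mean=d,
        hippo_rd_sd=0.0,
    )
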