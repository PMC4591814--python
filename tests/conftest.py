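import numpy as np
import pytest
from hypothesis import settings

import tlsquant as tq

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def substrates():
    return tq.standard_substrates()


@pytest.fixture(scope="session")
def sub14tg(substrates):
    return substrates["14/Tg"]


@pytest.fixture(scope="session")
def sub14t(substrates):
    return substrates["14/T"]


@pytest.fixture(scope="session")
def wt_profiles(sub14tg):
    """WT-like damaged/undamaged profiles on the 14-mer substrates."""
    return tq.example_profiles(sub14tg.k, sub14tg.lesion_n)["WT-like"]


def lane_from_distribution(dist, substrate, scale=1000.0, **meta):
    """Noiseless lane whose band intensities follow an exact distribution."""
    defaults = dict(
        lane_id="analytic",
        enzyme="enzyme",
        substrate_name=substrate.name,
        time_min=1.0,
        replicate=1,
    )
    defaults.update(meta)
    return tq.Lane(intensities=np.asarray(dist) * scale, **defaults)


@pytest.fixture(scope="session")
def make_analytic_lane():
    return lane_from_distribution
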