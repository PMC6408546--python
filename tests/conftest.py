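import numpy as np
import pytest

from stemflux.chamber import ChamberSpec
from stemflux.synthetic import SynthConfig


@pytest.fixture
def chamber() -> ChamberSpec:
    return ChamberSpec(collar_area=0.03178, system_volume=0.004,
                       pressure=101325.0, air_temperature=298.15)


@pytest.fixture
def short_config() -> SynthConfig:
    """A 20-day campaign with in-span gap windows (fast unit-test runs)."""
    return SynthConfig(
        n_days=20,
        ghg_gap_windows=[("2017-04-10", "2017-04-11")],
        sf_gap_windows=[("2017-04-12", "2017-04-13")],
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170401)
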