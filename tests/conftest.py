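import numpy as np
import pytest

from irisdose.harness import (HarnessConfig, build_beam_data,
                              commission_source)
from irisdose.source import default_spectrum, generate_phase_space
from irisdose.transport import Beam, BeamPlan


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spectrum():
    return default_spectrum()


@pytest.fixture(scope="session")
def ps60_small(spectrum):
    """A modest 60 mm phase space shared by fast unit tests."""
    return generate_phase_space(spectrum, focal_spot_sigma=1.5,
                                plane_z=700.0, n=100_000, seed=42)


@pytest.fixture(scope="session")
def harness_config():
    """Moderate-statistics settings for shared commissioning fixtures."""
    return HarnessConfig(seed=7, n_phase_space=200_000, histories=300_000,
                         batches=6, calibration_histories=400_000,
                         calibration_max_rel_uncertainty=0.05)


@pytest.fixture(scope="session")
def commissioned(harness_config):
    mc, diag = commission_source([25.0, 60.0], harness_config)
    return mc, diag


@pytest.fixture(scope="session")
def beam_data_60(commissioned, harness_config):
    mc, _ = commissioned
    return build_beam_data(mc, [60.0], harness_config)


@pytest.fixture(scope="session")
def water_dose_60(commissioned):
    """Calibrated 60 mm water-tank dose at SSD 800 (commissioning tank)."""
    from irisdose.geometry import make_water_tank

    mc, _ = commissioned
    s = 5.0
    nxy = 40
    origin = np.array([-(nxy - 1) * s / 2.0, -(nxy - 1) * s / 2.0,
                       800.0 + s / 2.0])
    tank = make_water_tank((200.0, 200.0, 310.0), (s, s, s),
                           origin_mm=origin)
    plan = BeamPlan(beams=[Beam(isocenter=np.array([0.0, 0.0, 800.0]),
                                direction=np.array([0.0, 0.0, 1.0]),
                                collimator_diameter=60.0, mu=1.0)])
    return mc.engine(seed=99)(tank, plan)
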