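import numpy as np
import pytest

import oxyresp as ox


@pytest.fixture(scope="session")
def protocol_5s():
    """Default chamber protocol at 5 s sampling (fast to simulate)."""
    return ox.ProtocolConfig(sample_interval_s=5.0)


@pytest.fixture(scope="session")
def noiseless_scenario():
    return ox.ScenarioConfig(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_fish(protocol_5s, noiseless_scenario):
    """One noiseless fish: truth, intermittent trace and closed trace.

    The recovery half-life is short enough that the post-chase excess has
    fully decayed well before the end of the run, so late-cycle uptake
    equals the standard metabolic rate to floating-point precision.
    """
    truth = ox.FishTruth(recovery_halflife_h=0.25)
    inter = ox.simulate_intermittent_trace(
        truth, protocol_5s, scenario=noiseless_scenario
    )
    closed = ox.simulate_closed_phase(truth, protocol_5s, noiseless_scenario)
    return truth, inter, closed


@pytest.fixture(scope="session")
def conditions_24c():
    return ox.WaterConditions(temperature=24.0, barometric_pressure=101.325)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
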