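import numpy as np
import pytest

from cvrkit.physio import EtCO2Trace
from cvrkit.synthetic import (
    SimulationConfig,
    make_gas_paradigm,
    simulate_etco2,
    simulate_phantom_masks,
)


@pytest.fixture(scope="session")
def paradigm():
    """The default hypercapnia protocol: 2 min air / 3 min CO2 over 12 min."""
    return make_gas_paradigm(2, 3, 12)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(noise_sd_pct=0.0, drift_pct_per_scan=0.0, seed=11)


@pytest.fixture(scope="session")
def etco2_trace(paradigm, noiseless_config):
    return simulate_etco2(paradigm, noiseless_config)


@pytest.fixture(scope="session")
def phantom():
    return simulate_phantom_masks(shape=(32, 32, 32), spacing_mm=(2.5, 2.5, 2.5), seed=3)


@pytest.fixture()
def linear_trace():
    """Simple two-point trace rising 38 -> 48 mmHg over 10 s."""
    return EtCO2Trace(times_s=np.array([0.0, 10.0]), values_mmHg=np.array([38.0, 48.0]))
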