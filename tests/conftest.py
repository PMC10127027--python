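import pytest

from hippoconn.preprocess import BandDefinition
from hippoconn.synthetic import PHASES, SimulationConfig


@pytest.fixture
def theta() -> BandDefinition:
    return BandDefinition("theta", 5.0, 12.0)


@pytest.fixture
def tiny_sim_config() -> SimulationConfig:
    """Small, fast session: 6 channels, 2 trials per phase, short trials."""
    return SimulationConfig(
        n_channels=6,
        trials_per_phase={p: 2 for p in PHASES},
        trial_duration_s=(4.0, 5.0),
        gap_s=0.5,
    )
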