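import numpy as np
import pytest

from ppgresp import PipelineConfig, SimulationConfig, simulate_ppg


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_sim():
    """2.5-minute noise-free record with all three modulations, hr 75 / rr 15."""
    cfg = SimulationConfig(hr_bpm=75.0, rr_bpm=15.0, duration_s=150.0, seed=5)
    return simulate_ppg(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Same physiology at 20 dB SNR."""
    cfg = SimulationConfig(
        hr_bpm=75.0, rr_bpm=15.0, snr_db=20.0, duration_s=150.0, seed=5
    )
    return simulate_ppg(cfg)
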