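import numpy as np
import pytest

from serpbci.classify import ChannelDataset
from serpbci.protocol import ProtocolConfig, generate_schedule
from serpbci.synth import SepTemplate, SubjectModel, simulate_recording


@pytest.fixture(scope="session")
def small_schedule():
    """One-block schedule (300 stimuli) — enough for pipeline geometry tests."""
    return generate_schedule(ProtocolConfig(n_blocks=1, seed=7))


@pytest.fixture(scope="session")
def two_block_schedule():
    """Two blocks so both attention conditions occur (all four clusters)."""
    return generate_schedule(ProtocolConfig(n_blocks=2, seed=7))


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, blink-free subject with a strong attention effect."""
    return SubjectModel(attention_gain=2.0, noise_sd_uV=0.0, blink_rate_hz=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_recording(two_block_schedule, clean_subject):
    return simulate_recording(two_block_schedule, clean_subject)


def make_dataset(rng: np.random.Generator, m: int = 10, shift: float = 2.0,
                 noise: float = 0.5, channel: str = "C3", n_avg: int = 10) -> ChannelDataset:
    """Small synthetic grouped-sERP dataset with an attention effect of size
    ``shift`` confined to decimated samples 20..29 of the attended D response."""
    signal = np.zeros(60)
    signal[20:30] = shift
    serps = {
        "ADSD": signal + noise * rng.standard_normal((m, 60)),
        "ADSV": noise * rng.standard_normal((m, 60)),
        "AVSD": noise * rng.standard_normal((m, 60)),
        "AVSV": noise * rng.standard_normal((m, 60)),
    }
    return ChannelDataset(channel, serps, n_avg)
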