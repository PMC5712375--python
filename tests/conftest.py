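import numpy as np
import pytest

from neurogait import SynthConfig, Trial, generate_dataset, standard_1010_layout
from neurogait.layout import ANALYSIS_ELECTRODES

FS = 500.0


def tone(freq_hz: float, amplitude: float = 1.0, duration_s: float = 1.0, phase: float = 0.0):
    t = np.arange(int(round(duration_s * FS))) / FS
    return amplitude * np.cos(2 * np.pi * freq_hz * t + phase)


@pytest.fixture(scope="session")
def layout():
    return standard_1010_layout()


@pytest.fixture(scope="session")
def small_dataset():
    """Nine-channel synthetic dataset at the default (strong-ERD) conditions."""
    cfg = SynthConfig(n_trials=4, channels=ANALYSIS_ELECTRODES, seed=11)
    trials, manifest = generate_dataset(cfg)
    return trials, manifest, cfg


@pytest.fixture()
def simple_trial():
    """Deterministic 3-channel trial with one start/stop pair for protocol tests."""
    rng = np.random.default_rng(3)
    data = rng.standard_normal((3, int(30 * FS)))
    from neurogait import EventMark

    return Trial(
        data=data,
        sample_rate=FS,
        channel_names=["Cz", "C3", "C4"],
        events=[EventMark("start", 12.0), EventMark("stop", 24.0)],
    )
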