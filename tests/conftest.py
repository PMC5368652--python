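import numpy as np
import pytest

from prr.core import EpochSet, Signal
from prr.synth import GroundTruth, SessionConfig, generate_lfp, generate_respiration, generate_session


@pytest.fixture(scope="session")
def default_truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture(scope="session")
def short_session():
    """A 120 s synthetic session with a handful of units, shared across
    tests that only read from it."""
    config = SessionConfig(duration_s=120.0, n_pyr=4, n_in=2,
                           pyr_coupled_fraction=0.5, in_coupled_fraction=0.5)
    return generate_session(config, seed=11)


@pytest.fixture(scope="session")
def coupled_lfp(default_truth):
    """120 s LFP + respiration pair with all couplings at their defaults."""
    resp = generate_respiration(120.0, 1000.0, 3.5, 0.1, seed=7)
    lfp = generate_lfp(120.0, 1000.0, default_truth, resp)
    return lfp, resp


def tone(freq_hz: float, duration_s: float = 10.0, fs: float = 1000.0,
         amp: float = 1.0, phase: float = 0.0) -> Signal:
    t = np.arange(int(duration_s * fs)) / fs
    return Signal(amp * np.cos(2 * np.pi * freq_hz * t + phase), fs, label=f"{freq_hz}Hz")


@pytest.fixture
def full_epochs():
    def _make(signal: Signal) -> EpochSet:
        return EpochSet(((signal.t0, signal.t0 + signal.duration),))
    return _make
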