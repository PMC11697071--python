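import numpy as np
import pytest

from somnopac import PacInjectionSpec, StateProfile, synthesize_state_segment
from somnopac.synthetic import default_profiles

RATE = 400.0


@pytest.fixture(scope="session")
def rem_profile() -> StateProfile:
    return default_profiles()["REM"]


@pytest.fixture(scope="session")
def coupled_signal(rem_profile):
    """60-s REM-like signal with strong 8 Hz -> 100 Hz coupling."""
    pac = PacInjectionSpec(coupling_strength=0.8)
    return synthesize_state_segment(rem_profile, pac, 60.0, RATE, seed=11)


def make_tone(freq_hz: float, duration_s: float, rate: float = RATE, amplitude: float = 1.0):
    t = np.arange(int(round(duration_s * rate))) / rate
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
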