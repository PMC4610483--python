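import numpy as np
import pytest

from spiralkin.spiral_data import SpiralTrial
from spiralkin.synthetic import PRESETS, SimProfile, simulate_trial


def noise_free_profile(pitch=10.0, **overrides) -> SimProfile:
    """A profile with every stochastic term switched off."""
    params = dict(
        label="healthy",
        pitch=pitch,
        speed_noise_sd=0.0,
        hesitation_rate=0.0,
        hf_irregularity_amp=0.0,
        tremor_amp=0.0,
        asymmetry_bias=0.0,
        jitter_sd=0.0,
    )
    params.update(overrides)
    return SimProfile(**params)


@pytest.fixture
def ideal_trial() -> SpiralTrial:
    """Noise-free outward Archimedean trace starting at the centre."""
    return simulate_trial(noise_free_profile(), duration=10.0, rate=10.0, seed=0)


@pytest.fixture
def archimedes_trial_factory():
    """Exact Archimedean trace at constant angular rate about a centre."""

    def make(pitch=2.0, omega=1.0, n=100, dt=0.1, center=(0.0, 0.0), phi0=0.0):
        t = np.arange(n) * dt
        phi = phi0 + omega * t
        r = pitch * phi
        return SpiralTrial(
            x=center[0] + r * np.cos(phi),
            y=center[1] + r * np.sin(phi),
            t=t,
        )

    return make


@pytest.fixture
def brady_trial() -> SpiralTrial:
    return simulate_trial(PRESETS["bradykinetic"], seed=11)


@pytest.fixture
def dysk_trial() -> SpiralTrial:
    return simulate_trial(PRESETS["dyskinetic"], seed=12)
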