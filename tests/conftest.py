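import numpy as np
import pytest

import hemisync as hs


@pytest.fixture(scope="session")
def layout():
    return hs.default_layout()


@pytest.fixture(scope="session")
def sim_cfg():
    """Short simulation at a reduced working rate for fast tests."""
    return hs.SimulationConfig(seed=11, duration=30.0, rate=1000.0)


@pytest.fixture(scope="session")
def percept_events(sim_cfg):
    return hs.generate_percept_stream(sim_cfg)


@pytest.fixture(scope="session")
def recording(sim_cfg, percept_events):
    return hs.generate_recording(
        sim_cfg, percept_events, session="in_phase", condition="sham"
    )


def sine_recording(freqs_amps, rate=1000.0, duration=4.0, layout=None, noise=0.0, seed=0):
    """Helper: 31-channel recording holding the same sinusoid mixture."""
    layout = layout or hs.default_layout()
    t = np.arange(int(duration * rate)) / rate
    sig = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    rng = np.random.default_rng(seed)
    data = np.tile(sig, (layout.n_channels, 1))
    if noise:
        data = data + rng.standard_normal(data.shape) * noise
    return hs.Recording(data=data, rate=rate, layout=layout)
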