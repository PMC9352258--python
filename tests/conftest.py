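import numpy as np
import pytest

import gndfit as g


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_event_trace(
    width=20e-6,
    depth=30.0,
    noise_sd=3.0,
    fs=2e6,
    i_open=100.0,
    seed=0,
    duration=6e-3,
):
    """One centered rectangular blockade, optionally noisy."""
    cfg = g.SimConfig(
        fs=fs,
        duration=duration,
        i_open=i_open,
        noise_sd=noise_sd,
        pulses=[g.Pulse(duration / 2 - width / 2, width, depth)],
        seed=seed,
    )
    return g.synthesize(cfg)


@pytest.fixture
def event_trace_factory():
    return make_event_trace
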