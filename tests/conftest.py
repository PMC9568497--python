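import numpy as np
import pytest

from gazecue import (DetectorParams, ScreenGeometry, TimelineJitter,
                     TraceSimConfig, make_timeline, simulate_trace)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return ScreenGeometry()


@pytest.fixture
def params():
    return DetectorParams()


@pytest.fixture
def zero_jitter_timeline():
    """Deterministic timeline at the mean anchor times (SOA 200 ms)."""
    return make_timeline(200, TimelineJitter(sd_ms=0.0),
                         np.random.default_rng(0))


def make_traces(n, seed=0, cfg=None, soa=500, cue="right"):
    """Batch of simulated traces with their ground-truth events."""
    rng = np.random.default_rng(seed)
    cfg = cfg or TraceSimConfig()
    out = []
    for i in range(n):
        timeline = make_timeline(soa, rng=rng)
        trace, truth = simulate_trace(cfg, timeline, cue, rng=rng,
                                      trial_id=f"t{i:03d}")
        out.append((trace, truth, timeline))
    return out


@pytest.fixture(scope="session")
def simulated_batch():
    """20 default-config traces shared across detector tests."""
    return make_traces(20, seed=2024)
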