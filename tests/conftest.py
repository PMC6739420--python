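import numpy as np
import pytest

import collic
from collic.synthetic import HeadEvent


@pytest.fixture
def flat_trace():
    """10 s noiseless trace with no events."""
    trace, _ = collic.generate_head_trace(10.0, seed=0)
    return trace


@pytest.fixture
def single_bout_trace():
    """One 20 deg yaw bout of 200 ms starting at 3 s, otherwise flat."""
    return collic.generate_head_trace(
        10.0, [HeadEvent("yaw", 3.0, 20.0, 200.0)], seed=0
    )


def random_trace(seed: int, duration_s: float = 10.0) -> collic.EulerTrace:
    """Wandering noisy trace for detector equivalence/property tests."""
    rng = np.random.default_rng(seed)
    n_events = rng.integers(0, 5)
    events = []
    t = 1.0
    for _ in range(n_events):
        t += rng.uniform(0.3, 1.5)
        dur = rng.uniform(120, 500)
        if t + dur / 1000 > duration_s - 1:
            break
        events.append(
            HeadEvent(
                rng.choice(["yaw", "pitch", "roll"]),
                float(t),
                float(rng.uniform(-30, 30)),
                float(dur),
            )
        )
        t += dur / 1000
    trace, _ = collic.generate_head_trace(
        duration_s, events, noise_sd=0.3, wander_sd=1.0, seed=seed
    )
    return trace
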