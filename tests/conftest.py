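"""Shared fixtures: small simulated sessions and toy training data.

Everything is generated programmatically with fixed seeds; session-scoped
fixtures are reused across test modules to keep the suite fast.
"""

import numpy as np
import pytest

import headernet as hn
from headernet import prep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def waveform_params():
    return hn.simulator.WaveformParams()


@pytest.fixture(scope="session")
def small_session(waveform_params):
    """A compact session: 20 headers, ~10 spurious per header, both filters hit."""
    cfg = hn.SessionConfig(scheduled_headers=20, nh_per_vh=10.0,
                           out_of_match_events=30, off_pitch_events=15)
    events, video, schedule, truth = hn.simulate_session(cfg, waveform_params, 99)
    return cfg, events, video, schedule, truth


@pytest.fixture(scope="session")
def labeled_small(small_session):
    _, events, video, schedule, _ = small_session
    labeled, report = hn.build_ground_truth(events, video, schedule)
    return labeled, report


def make_toy_dataset(n_per_class: int, seed: int = 0):
    """Linearly separable toy: smooth header pulses vs spike non-headers."""
    params = hn.simulator.WaveformParams()
    rng = np.random.default_rng(seed)
    X, y = [], []
    for _ in range(n_per_class):
        X.append(hn.simulate_header_trace(params, rng))
        y.append(1)
        X.append(hn.simulate_nonheader_trace(params, rng, archetype="spike"))
        y.append(0)
    X = np.stack([prep.znormalize(x) for x in X])
    return X, np.array(y)


@pytest.fixture(scope="session")
def toy_data():
    """200-event toy split into train/val halves."""
    X, y = make_toy_dataset(100, seed=5)
    return (X[:140], y[:140]), (X[140:], y[140:])
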