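"""Shared fixtures: scaled-down architectures and short recordings.

Most training-mechanics tests run on a 1400-sample window variant of the
architecture (the shortest input the four-deep conv stack accepts comfortably)
so the full suite stays fast; shape- and protocol-critical tests use the real
7000-sample geometry.
"""

import numpy as np
import pytest

import edassl as e

SMALL_LEN = 1400
SMALL_HORIZON = 8


@pytest.fixture(scope="session")
def small_pretext_arch():
    return e.PretextArchitecture(input_len=SMALL_LEN, output_units=SMALL_HORIZON)


@pytest.fixture(scope="session")
def small_downstream_arch():
    return e.DownstreamArchitecture(input_len=SMALL_LEN)


@pytest.fixture(scope="session")
def small_params():
    return e.WindowingParams(window_len=SMALL_LEN, horizon=SMALL_HORIZON, stride=100)


@pytest.fixture(scope="session")
def tiny_recording():
    """Four 10 s segments (28 000 samples at 700 Hz) with varied arousal."""
    segments = tuple(
        e.SegmentSpec(duration=10.0, arousal=a, likert_answers=ans)
        for a, ans in [
            (0.0, (1, 1, 2, 1, 1, 1)),
            (0.9, (4, 3, 4, 4, 3, 4)),
            (0.3, (2, 2, 2, 3, 2, 2)),
            (0.7, (3, 4, 3, 3, 4, 3)),
        ]
    )
    cfg = e.SimConfig(subject_seed=42, segments=segments)
    return e.simulate_subject(cfg)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_recording):
    scaled, _ = e.normalize_recording(tiny_recording)
    return e.dataset_from_recording(scaled)


@pytest.fixture(scope="session")
def tiny_windows(tiny_dataset, small_params):
    """20 small labelled windows (5 per segment) for question 1."""
    return e.make_labeled_windows(tiny_dataset, 1, small_params)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_dataset, small_params):
    return e.make_pretext_pairs(tiny_dataset.recording, small_params)


def assert_weights_equal(a, b):
    __tracebackhide__ = True
    assert len(a) == len(b)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
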