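import numpy as np
import pytest

from strokewave.stroke_detection import detect_stroke_events
from strokewave.synthetic import SessionParams, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A 12-stroke paired session with default noise (seed 5)."""
    return generate_session(SessionParams(n_strokes=12, stroke_rate_spm=32.0, seed=5))


@pytest.fixture(scope="session")
def small_events(small_session):
    return detect_stroke_events(small_session.accel)


@pytest.fixture(scope="session")
def clean_session():
    """A noise-free, jitter-free 10-stroke session at exactly 30 spm."""
    params = SessionParams(
        n_strokes=10,
        stroke_rate_spm=30.0,
        stroke_rate_sd_spm=0.0,
        noise_sd=0.0,
        seed=0,
    )
    return generate_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
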