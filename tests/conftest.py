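import numpy as np
import pytest

from camvitals.beats import detect_beats
from camvitals.preprocessing import band_limit
from camvitals.synthetic import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def clean_session():
    """2-minute single-ROI session at a constant 72 beats/min, light noise."""
    cfg = SyntheticConfig(duration_s=120.0, hr_trace=72.0, rr_trace=15.0,
                          noise_sd=0.05, seed=11, n_rois=1)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def clean_beats(clean_session):
    """Band-limited green-channel series and its detected beats."""
    session, truth = clean_session
    x = band_limit(session.subject_series[(1, "green")], session.fps)
    beats = detect_beats(x, session.fps)
    return x, beats, truth


def make_pulse(length: int = 15, upslope: int = 3) -> np.ndarray:
    """One raised-cosine pulse on an integer sample grid."""
    up = 0.5 * (1 - np.cos(np.pi * np.arange(upslope + 1) / upslope))
    down = 0.5 * (1 + np.cos(np.pi * np.arange(1, length - upslope) / (length - upslope)))
    return np.concatenate([up, down])
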