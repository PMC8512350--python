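import numpy as np
import pytest

from perclos.classify import build_templates, classify_sequence
from perclos.synthetic import (
    DROWSY_PROFILE,
    default_calibration_selections,
    generate_session,
    render_frames,
)


@pytest.fixture(scope="session")
def drowsy_session():
    """One seeded 120 s drowsy session: aperture signal plus ground truth."""
    aperture, gt = generate_session(DROWSY_PROFILE, duration_s=120.0, fps=60.0, seed=11)
    return aperture, gt


@pytest.fixture(scope="session")
def rendered_session(drowsy_session):
    """A 60 s rendered slice of the drowsy session, classified end to end.

    Returns (ground-truth mask slice, classified EyeStateSeries, frames).
    """
    aperture, gt = drowsy_session
    n = 3600
    ap = aperture[:n]
    frames, provider = render_frames(ap, seed=12)
    selections = default_calibration_selections(ap)
    calibration = build_templates(frames, selections)
    series = classify_sequence(frames, calibration, provider, fps=60.0, source_id="render")
    return gt.closed_mask()[:n], series, frames
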