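import numpy as np
import pytest

from zfeeg import AnimalProfile, TimelineMarks, bandpass
from zfeeg.detect import detect_events
from zfeeg.synthetic import generate_recording

FS = 250.0

#: Short session used by unit tests: 2-min control, injection, 90-s
#: stabilization, 15-min total.
SHORT_MARKS = TimelineMarks(injection_time=120.0, session_end=900.0)


@pytest.fixture(scope="session")
def short_marks():
    return SHORT_MARKS


@pytest.fixture(scope="session")
def planted_recording():
    """One 15-min recording with a handful of planted events (fs 250)."""
    profile = AnimalProfile(
        sex="male",
        count_fixed=4,
        duration_mean_s=25.0,
        duration_cv=0.3,
        latency_mean_s=120.0,
        latency_cv=0.3,
        onset_probs=(0.32, 0.39, 0.10, 0.19),
    )
    rec, truth = generate_recording(profile, SHORT_MARKS, FS, seed=42)
    return rec, truth


@pytest.fixture(scope="session")
def detected(planted_recording):
    rec, truth = planted_recording
    events = detect_events(bandpass(rec))
    return rec, truth, events


@pytest.fixture(scope="session")
def baseline_recording():
    """Baseline-only (non-responder) recording for specificity checks."""
    profile = AnimalProfile(sex="female", responder=False)
    rec, truth = generate_recording(profile, SHORT_MARKS, FS, seed=7)
    assert truth == []
    return rec
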