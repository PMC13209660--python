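import numpy as np
import pytest

from nirsleep.staging import SleepTimeline
from nirsleep.synthetic import (
    Event,
    NoiseParams,
    SubjectParams,
    social_paradigm,
)


@pytest.fixture
def constant_qs_timeline():
    return SleepTimeline(intervals=[(0.0, 600.0, "QS")])


@pytest.fixture
def sparse_schedule():
    """Events spaced far enough apart that their responses never overlap."""
    return [Event(40.0 + 60.0 * i, 8.0, "V") for i in range(4)]


@pytest.fixture
def noiseless_params():
    """Planted 0.8 uM response, cardiac pulse only (needed to pass QC)."""
    return SubjectParams(
        response_amplitude={"V": {"QS": 0.8}, "N": {"QS": 0.8}},
        noise_params=NoiseParams(
            cardiac_amp=0.004, resp_amp=0.0, drift_amp=0.0, white_amp=0.0
        ),
        artifact_rate_per_min={"QS": 0.0, "AS": 0.0, "awake": 0.0},
        seed=7,
    )


@pytest.fixture
def social():
    return social_paradigm()
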