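import numpy as np
import pytest

from oculosway import SubjectModel, build_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def quiet_subject():
    """Deterministic subject: no noise, no intrusions, fixed latency."""
    return SubjectModel(
        latency_mean=0.200,
        latency_sd=0.0,
        error_prob=0.0,
        gaze_noise_sd=0.0,
        intrusion_rate=0.0,
        pupil_noise_sd=0.0,
    )


@pytest.fixture
def schedule_2dp():
    return build_schedule("2D-P", seed=1)
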