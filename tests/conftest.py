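import warnings

import pytest

from frailsense.pipeline import extract_subject, simulate_subject
from frailsense.synth import GaitGroundTruth, simulate_gait


@pytest.fixture(scope="session")
def default_truth():
    return GaitGroundTruth(seed=7)


@pytest.fixture(scope="session")
def default_schedule(default_truth):
    return simulate_gait(default_truth)


@pytest.fixture(scope="session")
def default_record(default_truth):
    """One fully rendered synthetic subject at study-condition noise."""
    return simulate_subject(default_truth, "s00")


@pytest.fixture(scope="session")
def default_features(default_record):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_subject(default_record)


@pytest.fixture(scope="session")
def quiet_truth():
    """Noise-free ground truth for exact round-trip checks."""
    return GaitGroundTruth(
        seed=3,
        laser_noise_mm=0.0,
        imu_noise_dps=0.0,
        pose_noise_px=0.0,
        force_noise_n=0.0,
    )


@pytest.fixture(scope="session")
def quiet_schedule(quiet_truth):
    return simulate_gait(quiet_truth)
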