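import numpy as np
import pytest

from usradiomics import CohortConfig, TumorROI, simulate_cohort


def disk_mask(shape=(64, 64), center=None, radius=20.0):
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort used throughout the suite."""
    return CohortConfig(
        n_subjects=4,
        n_groups=2,
        frames_per_scan=3,
        image_size=(64, 64),
        tumor_radius_mean=14.0,
        tumor_radius_jitter=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def speckle_roi():
    """One deterministic speckled frame with a centered disk ROI."""
    rng = np.random.default_rng(11)
    frame = np.clip(100.0 * rng.rayleigh(scale=np.sqrt(2 / np.pi), size=(64, 64)), 0, 255)
    return frame, TumorROI(disk_mask())


@pytest.fixture(scope="session")
def disk_roi():
    return TumorROI(disk_mask(shape=(80, 80), radius=30.0))
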