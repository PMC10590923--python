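import numpy as np
import pytest

from noemri.phantom import (PhantomConfig, build_offset_schedule, default_wassr_schedule,
                            make_label_phantom, simulate_subject)


@pytest.fixture(scope="session")
def labels96():
    return make_label_phantom(96)


@pytest.fixture(scope="session")
def labels128():
    return make_label_phantom(128)


@pytest.fixture(scope="session")
def coarse_schedule():
    """Reduced-density schedule (still containing +/-3.5 ppm) for fast tests."""
    return build_offset_schedule([(0, 6, 0.25), (6, 10, 1.0), (10, 20, 2.0), (20, 100, 20.0)])


@pytest.fixture(scope="session")
def noiseless_subject(labels96, coarse_schedule):
    """One noiseless WT subject with zero B0 field."""
    cfg = PhantomConfig(size=96, noise_sd=0.0, b0_coeffs=np.zeros((1, 1)), n_subjects=1)
    subj, truth = simulate_subject(cfg, labels96, coarse_schedule, "WT", seed=5)
    return subj, truth, labels96


@pytest.fixture(scope="session")
def noisy_subject(labels96, coarse_schedule):
    """One WT subject with default noise and B0 field."""
    cfg = PhantomConfig(size=96, n_subjects=1)
    subj, truth = simulate_subject(cfg, labels96, coarse_schedule, "WT", seed=5)
    return subj, truth, labels96
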