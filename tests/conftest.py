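"""Shared fixtures: phantoms, paradigms and cached end-to-end studies."""

import numpy as np
import pytest

from somatomap.pipeline import StudyConfig, run_phantom_study
from somatomap.synthetic_data import make_er_paradigm, make_somatotopic_phantom


@pytest.fixture(scope="session")
def phantom():
    return make_somatotopic_phantom()


@pytest.fixture(scope="session")
def er_paradigms():
    return make_er_paradigm(2, seed=11)


@pytest.fixture(scope="session")
def study():
    """Default-noise end-to-end phantom study (seed 7)."""
    return run_phantom_study(seed=7)


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free study for exact-recovery checks."""
    cfg = StudyConfig(noise_sigma=0.0, drift_amplitude=0.0)
    return run_phantom_study(seed=3, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
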