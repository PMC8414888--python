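import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from restbci.cohort import SubjectProfile, default_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture
def quiet_profile():
    """A subject with sources but no background noise."""
    return SubjectProfile(subject_id=0, theta_level=1.5, alpha_level=1.0,
                          beta_level=0.4, regularity=0.6, erd_strength=0.5,
                          noise_scale=0.0)
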