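import numpy as np
import pytest

from symsig.generate import StudyConfig, simulate_study
from symsig.models import run_model_suite


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default conditions (20 pairs, seed 1)."""
    return simulate_study(StudyConfig(), seed=1)


@pytest.fixture(scope="session")
def default_suite(default_study):
    """The thirteen-model suite fitted on the default study (no bootstrap)."""
    return run_model_suite(default_study.signals, bootstrap_reps=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
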