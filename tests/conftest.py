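import numpy as np
import pytest

from manipkin.config import AnalysisConfig
from manipkin.event_metrics import analyze_trial
from manipkin.synthetic_data import SubjectParams, simulate_trial


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_trial():
    """Noise-free two-sided trial with default (study-mean) parameters."""
    return simulate_trial(SubjectParams(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_trial, default_config):
    trial, _ = default_trial
    return analyze_trial(trial, default_config)


@pytest.fixture(scope="session")
def single_sided_trial():
    """Noise-free left-only trial (no artifact, no right event)."""
    return simulate_trial(SubjectParams(seed=2, artifact_time=None))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
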