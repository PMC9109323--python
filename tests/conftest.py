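import numpy as np
import pytest

from lcsiq import DGPConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return DGPConfig()


@pytest.fixture(scope="session")
def matched_cohort(default_config):
    """Moment-matched cohort at the default study conditions."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def small_cohort():
    """A small stochastic cohort for fast fitting tests."""
    cfg = DGPConfig(n_bf=240, n_nobf=360, moment_matched=False, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_missing_values():
    """Six records, two missing cells: small enough for brute-force likelihood
    maximization, rich enough to exercise three missingness patterns."""
    return np.array([
        [1.0, 95.0, 101.0],
        [0.0, 88.0, 92.0],
        [1.0, 112.0, np.nan],
        [0.0, np.nan, 97.0],
        [1.0, 104.0, 109.0],
        [0.0, 91.0, 90.0],
    ])
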