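import numpy as np
import pytest

from bitecurve.generator import (
    ReferenceStats,
    build_parameter_distribution,
    sample_microstructure,
    sample_true_parameters,
)
from bitecurve.report import StudyConfig, run_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_profiles():
    """A modest generating sample shared by the slower integration tests."""
    return sample_microstructure(ReferenceStats(), 80, np.random.default_rng(11))


@pytest.fixture(scope="session")
def lode_dist(small_profiles):
    return build_parameter_distribution(small_profiles, "lode", np.random.default_rng(12))


@pytest.fixture(scope="session")
def quad_dist(small_profiles):
    return build_parameter_distribution(small_profiles, "quadratic", np.random.default_rng(13))


@pytest.fixture(scope="session")
def lode_true_cases(lode_dist):
    return sample_true_parameters(lode_dist, 20, np.random.default_rng(14))


@pytest.fixture(scope="session")
def quad_true_cases(quad_dist):
    return sample_true_parameters(quad_dist, 20, np.random.default_rng(15))


@pytest.fixture(scope="session")
def default_study():
    """The full default validation study (2 models x 3 conditions x 100
    cases with profile CIs), shared by the acceptance tests.  Returns the
    result together with its wall-clock runtime in seconds."""
    import time

    t0 = time.perf_counter()
    result = run_study(StudyConfig(), seed=1)
    return result, time.perf_counter() - t0
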