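import warnings

import numpy as np
import pytest

from fixedlinks import PopulationModel, SampleMoments, load_study_correlations


@pytest.fixture(autouse=True)
def _silence_correlation_metric_warning():
    # the fixture matrix is a correlation matrix; the pipeline warns on
    # purpose, which is noise for most tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fitting a correlation matrix")
        yield


@pytest.fixture(scope="session")
def full_moments() -> SampleMoments:
    """Bundled 8 x 8 correlation matrix, n = 200."""
    return load_study_correlations()


@pytest.fixture(scope="session")
def wmc_moments() -> SampleMoments:
    """5 x 5 working-memory block of the bundled matrix."""
    return load_study_correlations(wmc_only=True)


@pytest.fixture(scope="session")
def population() -> PopulationModel:
    return PopulationModel()


def random_spd(rng: np.random.Generator, p: int) -> np.ndarray:
    """Random well-conditioned symmetric positive definite matrix."""
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T / (p + 3)
    return S + 0.5 * np.eye(p)
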