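import numpy as np
import pytest

from rsifit import BValueSchedule, CompartmentParams


@pytest.fixture(scope="session")
def schedule() -> BValueSchedule:
    return BValueSchedule()


@pytest.fixture(scope="session")
def study_scores_labels():
    """Binary smoking scores and subtype labels reconstructed from the
    study's 2x2 counts: 21/30 SCC smokers, 21/67 AC smokers (SCC=1)."""
    scores = np.r_[np.ones(21), np.zeros(9), np.ones(21), np.zeros(46)]
    labels = np.r_[np.ones(30, int), np.zeros(67, int)]
    return scores, labels


def random_simplex(rng, n=1):
    """Uniform draws on the unit 2-simplex."""
    e = rng.exponential(size=(n, 3))
    return e / e.sum(axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def mixed_params():
    return CompartmentParams(0.5, 0.3, 0.2, S0=1000.0)
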