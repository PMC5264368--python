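import numpy as np
import pytest

from pcavbcm import fit_pca, load_cohort, load_reference_factors
from pcavbcm.cohort import SPEECH_MEASURES


@pytest.fixture(scope="session")
def cohort():
    return load_cohort()


@pytest.fixture(scope="session")
def records(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def scores(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def reference():
    return load_reference_factors()


@pytest.fixture(scope="session")
def speech_model(scores):
    return fit_pca(scores[SPEECH_MEASURES])


@pytest.fixture(scope="session")
def omnibus_model(scores):
    return fit_pca(scores)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)
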