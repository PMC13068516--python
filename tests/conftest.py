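import numpy as np
import pytest

from ahp_prefs import load_fixture_cohort
from ahp_prefs.regression import covariate_frame


@pytest.fixture(scope="session")
def fixture_cohort():
    """The bundled 26-respondent survey cohort."""
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_covariates(fixture_cohort):
    return covariate_frame(fixture_cohort.participants)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
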