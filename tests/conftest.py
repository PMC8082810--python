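import numpy as np
import pytest

from swe_response.cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Default-configuration cohort (62 patients, Table-style missingness)."""
    return generate_cohort(default_config(), seed=20210429 % 2**31)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
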