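import numpy as np
import pytest

from umasurv import UMAParameters, fixtures_skin, fixtures_table1


@pytest.fixture(scope="session")
def sw1573() -> UMAParameters:
    return fixtures_table1()[0]


@pytest.fixture(scope="session")
def table1_params():
    return fixtures_table1()


@pytest.fixture(scope="session")
def skin_params():
    return fixtures_skin()


@pytest.fixture(scope="session")
def random_clinical_params():
    """Seeded sample of admissible (gamma, n) pairs spanning the fitted range."""
    rng = np.random.default_rng(20260930)
    return [
        UMAParameters(rng.uniform(0.1, 2.3), rng.uniform(0.2, 60.0))
        for _ in range(100)
    ]
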