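import warnings

import pytest

from drscreen import bundled_life_table, load_scenario


@pytest.fixture(scope="session")
def base_inputs():
    return load_scenario("base_case")


@pytest.fixture(scope="session")
def life_table():
    return bundled_life_table()


@pytest.fixture(autouse=True)
def _silence_age30_approximation_warning():
    # the age_30 scenario intentionally warns that its baseline distribution
    # is an approximation; tests exercising it don't need the noise
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*approximation.*", category=UserWarning)
        yield
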