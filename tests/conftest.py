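import matplotlib

matplotlib.use("Agg")

import pytest

from surgdelay import (
    GompertzParams,
    GrowthParams,
    country_population,
    load_delay_distribution,
)


@pytest.fixture(scope="session")
def growth_params():
    return GrowthParams()


@pytest.fixture(scope="session")
def gompertz_params():
    return GompertzParams()


@pytest.fixture(scope="session")
def us_population():
    return country_population("us")


@pytest.fixture(scope="session")
def us_distribution():
    return load_delay_distribution("us")


@pytest.fixture(scope="session")
def germany_population():
    return country_population("germany")


@pytest.fixture(scope="session")
def germany_distribution():
    return load_delay_distribution("germany")
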