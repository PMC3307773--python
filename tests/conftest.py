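import pytest

from complexwalk import default_config, flag_background, generate_study, load_table1_fixture
from complexwalk.walk import load_table2_catalog


@pytest.fixture(scope="session")
def table1():
    """The packaged reference matrix with background flags applied."""
    return flag_background(load_table1_fixture())


@pytest.fixture(scope="session")
def catalog():
    return load_table2_catalog()


@pytest.fixture(scope="session")
def noise_free_study():
    """One simulated study with the observation noise and decoys off."""
    return generate_study(default_config(seed=11).noise_free())


@pytest.fixture(scope="session")
def noisy_study():
    return generate_study(default_config(seed=11))
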