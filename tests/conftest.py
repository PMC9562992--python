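import pytest
from hypothesis import settings

from gaavar import VCEPProfile, calibrate

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")
from gaavar.synth import write_published_fixtures
from gaavar.tables import control_panel, tested_observations


@pytest.fixture
def panel():
    return control_panel()


@pytest.fixture
def observations():
    return tested_observations()


@pytest.fixture
def cal(panel):
    return calibrate(panel)


@pytest.fixture
def vcep():
    return VCEPProfile()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    write_published_fixtures(d)
    return d
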