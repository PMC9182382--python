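import pytest

from mlcqrar import load_fixture
from mlcqrar.pipeline import load_reported_stats


@pytest.fixture(scope="session")
def table():
    """The embedded 15-compound study dataset."""
    return load_fixture()


@pytest.fixture(scope="session")
def reported():
    """Published statistic blocks, printed precision preserved."""
    return load_reported_stats()
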