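import pytest

from cdftkit import taltobulin_fixture
from cdftkit.synthetic import write_bundle


@pytest.fixture(scope="session")
def bundle():
    """The Taltobulin analysis bundle (seed 1) shared across tests."""
    return taltobulin_fixture(seed=1)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The bundle serialized to plain-text artifacts on disk."""
    directory = tmp_path_factory.mktemp("bundle")
    return write_bundle(bundle, directory)
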