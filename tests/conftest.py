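import pytest

from patchrecovery import generate_fixture_registry


@pytest.fixture(scope="session")
def registry():
    """Bundled placeholder parameter registry (two seagrass-like species)."""
    return generate_fixture_registry(seed=0)
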