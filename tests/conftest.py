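import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")

from trialmatch.ontology import load_default_index
from trialmatch.pipeline import build_resources


@pytest.fixture(scope="session")
def index():
    return load_default_index()


@pytest.fixture(scope="session")
def resources():
    return build_resources()
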