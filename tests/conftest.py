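import pytest

from recsup import synth


@pytest.fixture(scope="session")
def demo_spec():
    return synth.default_spec(seed=0)


@pytest.fixture(scope="session")
def demo_pair(demo_spec):
    """The default synthetic chromosome pair (built once per session)."""
    return synth.make_chromosome_pair(demo_spec)


@pytest.fixture(scope="session")
def demo_maps(demo_spec):
    return synth.make_maps(demo_spec)
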