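import pytest

from caspec import RegionAligner, make_test_region


@pytest.fixture(scope="session")
def region():
    """A 250 bp random region with a '+'-strand protospacer planted mid-way."""
    return make_test_region(seed=1)


@pytest.fixture(scope="session")
def aligner(region):
    return RegionAligner({region.name: region})
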