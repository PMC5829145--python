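import pytest

from dtgraph import SpaceSpec


@pytest.fixture(scope="session")
def rnniu():
    return SpaceSpec.rnniu()


@pytest.fixture(scope="session")
def rnni():
    return SpaceSpec.rnni()


@pytest.fixture(scope="session")
def nni():
    return SpaceSpec.nni()


@pytest.fixture(scope="session")
def dtt2():
    return SpaceSpec.dtt(2)


@pytest.fixture(scope="session")
def dttu2():
    return SpaceSpec.dttu(2)


#: (space, largest n at which the whole space is enumerated in tests)
ENUMERABLE = [
    (SpaceSpec.rnniu(), 5),
    (SpaceSpec.rnni(), 4),
    (SpaceSpec.nni(), 5),
    (SpaceSpec.dttu(2), 4),
    (SpaceSpec.dtt(2), 3),
]
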