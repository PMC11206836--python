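import pytest

from cbzpbpk import load_compound, load_physiology, compute_kp_set


@pytest.fixture(scope="session")
def cbz():
    return load_compound("carbamazepine")


@pytest.fixture(scope="session")
def cbze():
    return load_compound("carbamazepine_epoxide")


@pytest.fixture(scope="session")
def phys():
    return load_physiology()


@pytest.fixture(scope="session")
def cbz_kps(cbz, phys):
    return compute_kp_set(cbz, phys)
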