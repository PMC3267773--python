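import numpy as np
import pytest

from helixsynergy.helix_geometry import BindingSite, HelixParameters, SiteArrangement


@pytest.fixture
def helix() -> HelixParameters:
    return HelixParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def make_pair(c2c: int, site_len: int = 17, twist: float = 36.0) -> SiteArrangement:
    """Two equal-length sites with the given center-to-center distance."""
    params = HelixParameters(twist_per_bp=twist)
    a = BindingSite("A", start=1, length=site_len)
    b = BindingSite("B", start=1 + c2c, length=site_len)
    return SiteArrangement(sites=(a, b), params=params)


@pytest.fixture
def pair_factory():
    return make_pair
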