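import pytest

from emoug import make_joint


@pytest.fixture(scope="session")
def uniform_joint():
    """Both emotional parameters iid uniform on [0, 1]."""
    return make_joint("uniform")


@pytest.fixture(scope="session")
def gaussian_joint():
    """Both parameters iid untruncated normal N(1/2, 1/6)."""
    return make_joint("normal", mu=0.5, sigma=1.0 / 6.0)
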