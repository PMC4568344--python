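import pytest

from gradewalk import BodyParams


@pytest.fixture
def body():
    """Per-unit-mass walker with the default 0.9 m leg."""
    return BodyParams(mass=1.0, leg_length=0.9)


@pytest.fixture
def heavy_body():
    return BodyParams(mass=70.0, leg_length=0.9)
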