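import pytest

from malatnet import build_nsclc_model, load_marker_map
from malatnet.model import parse_model

TOY_CASCADE = """\
A, 1, input
B, 1 : A
C, 1 : B & !A
"""

# two mutually inhibiting nodes: the minimal bistable switch
TOY_SWITCH = """\
A, 1 : !B
B, 1 : !A
"""

# negative 2-node loop: A activates B, B inhibits A
TOY_NEGLOOP = """\
A, 1 : !B
B, 1 : A
"""


@pytest.fixture(scope="session")
def nsclc():
    return build_nsclc_model()


@pytest.fixture(scope="session")
def markers():
    return load_marker_map()


@pytest.fixture()
def toy_cascade():
    return parse_model(TOY_CASCADE)


@pytest.fixture()
def toy_switch():
    return parse_model(TOY_SWITCH)


@pytest.fixture()
def toy_negloop():
    return parse_model(TOY_NEGLOOP)
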