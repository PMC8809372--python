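import pytest

from neuroqsp import toy_cipn_network
from neuroqsp.logic import parse_bnet


@pytest.fixture(scope="session")
def fixture_network():
    return toy_cipn_network()


@pytest.fixture()
def toggle_network():
    return parse_bnet("A, !B\nB, !A")


@pytest.fixture()
def or_gate_network():
    # apoptosis fires on either the cytokine input or drug-induced ROS
    return parse_bnet(
        "TNFa, TNFa\n"
        "Proteasome, Proteasome\n"
        "ROS, !Proteasome\n"
        "Apoptosis, TNFa | ROS\n"
    )
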