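import pytest

from wormbot.config import RunConfig
from wormbot.connectome import Connectome, NeuronRecord, SynapseRecord
from wormbot.membrane import (
    CELEGANS_CONSTANTS,
    NeuronParams,
    classical_squid_params,
)
from wormbot.network import build_network


@pytest.fixture
def squid():
    return classical_squid_params()


def make_chain_connectome(weight: float = 3.0, polarity: int = +1) -> Connectome:
    """S0 -> I0 -> M0 excitatory chain with strong relay weights."""
    return Connectome(
        neurons=[
            NeuronRecord("S0", "sensory"),
            NeuronRecord("I0", "interneuron"),
            NeuronRecord("M0", "motor"),
        ],
        synapses=[
            SynapseRecord("S0", "I0", +1, weight),
            SynapseRecord("I0", "M0", polarity, weight),
        ],
    )


def make_pair_connectome(polarity: int = +1, weight: float = 2.0) -> Connectome:
    """PRE -> POST two-neuron fixture."""
    return Connectome(
        neurons=[NeuronRecord("PRE", "sensory"), NeuronRecord("POST", "motor")],
        synapses=[SynapseRecord("PRE", "POST", polarity, weight)],
    )


#: high potassium conductance makes the response graded (no regenerative
#: spike), giving smooth trajectories where pointwise convergence tolerances
#: are meaningful; transmission still happens once V crosses -30 mV
GRADED_PARAMS = NeuronParams(gK=1500.0)


def make_graded_chain_connectome(weight: float = 3.0) -> Connectome:
    conn = make_chain_connectome(weight=weight)
    for rec in conn.neurons:
        rec.params = GRADED_PARAMS
    return conn


@pytest.fixture
def chain_network():
    return build_network(make_chain_connectome(), config=RunConfig())


@pytest.fixture
def graded_chain_network():
    return build_network(make_graded_chain_connectome(), config=RunConfig())


@pytest.fixture
def chain_params():
    """Per-neuron params of the chain fixture, for the reference oracle."""
    return [CELEGANS_CONSTANTS] * 3
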