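import pytest

from oglcnet.core import Arc, PetriNet, Place, Transition
from oglcnet.dynamics import SimulationSettings, simulate
from oglcnet.models import VARIANTS, build_model


@pytest.fixture(scope="session")
def variant_nets():
    return {v: build_model(v) for v in VARIANTS}


@pytest.fixture(scope="session")
def variant_trajectories(variant_nets):
    return {v: simulate(net) for v, net in variant_nets.items()}


@pytest.fixture
def decay_net():
    """Single place draining through one unit-rate sink: m(t) = e^{-t}."""
    return PetriNet(
        places=[Place("a", initial_tokens=1.0)],
        transitions=[Transition("t_dec", rate_constant=1.0, kind="sink")],
        arcs=[Arc("a", "t_dec")],
        name="decay",
    )


@pytest.fixture
def two_place_cycle():
    """Closed loop a -> t1 -> b -> t2 -> a conserving a + b."""
    return PetriNet(
        places=[Place("a", initial_tokens=2.0), Place("b", initial_tokens=0.5)],
        transitions=[Transition("t1"), Transition("t2")],
        arcs=[Arc("a", "t1"), Arc("t1", "b"), Arc("b", "t2"), Arc("t2", "a")],
        name="cycle",
    )
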