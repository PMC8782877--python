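import numpy as np
import pytest

from petrisens import Invariant, InvariantSet, PetriNet


def make_cycle(n: int = 3) -> PetriNet:
    """p1 -> t1 -> p2 -> t2 -> ... -> tn -> p1."""
    net = PetriNet(f"cycle{n}")
    for i in range(1, n + 1):
        net.add_place(f"p{i}")
        net.add_transition(f"t{i}")
    for i in range(1, n + 1):
        net.add_arc(f"p{i}", f"t{i}")
        net.add_arc(f"t{i}", f"p{i % n + 1}")
    return net


def make_chain() -> PetriNet:
    """t_in -> p -> t_out source/sink flow-through."""
    net = PetriNet("chain")
    net.add_place("p")
    net.add_transition("t_in")
    net.add_transition("t_out")
    net.add_arc("t_in", "p")
    net.add_arc("p", "t_out")
    return net


def make_diamond() -> PetriNet:
    """p1 -> {t1, t2} -> p2, p2 -> t3 -> p1."""
    net = PetriNet("diamond")
    net.add_place("p1")
    net.add_place("p2")
    for t in ("t1", "t2", "t3"):
        net.add_transition(t)
    net.add_arc("p1", "t1")
    net.add_arc("t1", "p2")
    net.add_arc("p1", "t2")
    net.add_arc("t2", "p2")
    net.add_arc("p2", "t3")
    net.add_arc("t3", "p1")
    return net


def invariant_set_from_supports(supports, order=None) -> InvariantSet:
    """Indicator-vector invariant set over the union of the given supports,
    for tests that exercise support-level analyses directly."""
    if order is None:
        order = tuple(sorted({t for sup in supports for t in sup}))
    idx = {t: k for k, t in enumerate(order)}
    invs = []
    for sup in supports:
        vec = [0] * len(order)
        for t in sup:
            vec[idx[t]] = 1
        invs.append(Invariant("t", tuple(vec), frozenset(sup)))
    return InvariantSet("t", invs, tuple(order), "supports")


@pytest.fixture
def three_cycle():
    return make_cycle(3)


@pytest.fixture
def diamond():
    return make_diamond()


@pytest.fixture
def chain():
    return make_chain()


@pytest.fixture(scope="session")
def p53_fragment():
    from petrisens import build_p53_fragment

    return build_p53_fragment()


@pytest.fixture(scope="session")
def fragment_invariants(p53_fragment):
    from petrisens import minimal_t_invariants

    return minimal_t_invariants(p53_fragment)


@pytest.fixture(scope="session")
def fixture_model():
    from petrisens import reduced_fixture_model

    return reduced_fixture_model()
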