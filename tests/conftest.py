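"""Shared fixtures: bundled models and small hand-built test networks."""

from fractions import Fraction

import pytest

from budcycle import bundled_fixture
from budcycle.netdef import EdgeSpec, NetworkModel, NodeSpec


@pytest.fixture(scope="session")
def li():
    return bundled_fixture("li")


@pytest.fixture(scope="session")
def mangla():
    return bundled_fixture("mangla")


@pytest.fixture(scope="session")
def proposed():
    return bundled_fixture("proposed")


def _ml_node(name, max_level=1, decay=False):
    th = [Fraction(1, 2), Fraction(3, 2)][:max_level]
    return NodeSpec(name, max_level, decay, tuple(th))


@pytest.fixture()
def sync_oscillator():
    """C drives A and B; A and B strongly inhibit each other: a synchronous
    2-cycle (both on -> both off -> both on ...)."""
    nodes = [_ml_node("A"), _ml_node("B"), _ml_node("C")]
    edges = [
        EdgeSpec("C", "A", Fraction(1)),
        EdgeSpec("C", "B", Fraction(1)),
        EdgeSpec("A", "B", Fraction(-3)),
        EdgeSpec("B", "A", Fraction(-3)),
        EdgeSpec("C", "C", Fraction(1)),
    ]
    return NetworkModel(
        "sync_osc", "multilevel", nodes, edges,
        states={"start": {"A": 1, "B": 1, "C": 1}},
    )


@pytest.fixture()
def async_oscillator():
    """A (self-degrading) copies B; B is the strong negation of A: a
    four-state asynchronous cycle driven by the constant node C."""
    nodes = [_ml_node("A", decay=True), _ml_node("B"), _ml_node("C")]
    edges = [
        EdgeSpec("B", "A", Fraction(1)),
        EdgeSpec("C", "B", Fraction(1)),
        EdgeSpec("A", "B", Fraction(-3)),
        EdgeSpec("C", "C", Fraction(1)),
    ]
    return NetworkModel(
        "async_osc", "multilevel", nodes, edges,
        states={"start": {"A": 0, "B": 1, "C": 1}},
    )


@pytest.fixture()
def two_node_chain():
    """A sustains itself and drives B: B can only rise after A."""
    nodes = [_ml_node("A"), _ml_node("B")]
    edges = [EdgeSpec("A", "A", Fraction(1)), EdgeSpec("A", "B", Fraction(1))]
    return NetworkModel(
        "chain", "multilevel", nodes, edges,
        states={"start": {"A": 1}},
    )
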