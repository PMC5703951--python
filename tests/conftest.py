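import numpy as np
import pytest

from adrkg import (
    ADR,
    DRUG,
    INDICATION,
    TARGET,
    KnowledgeGraph,
    NodeRef,
    PlantedSpec,
    generate_graph,
    select_predictors,
)


def D(i: str) -> NodeRef:
    return NodeRef(DRUG, i)


def A(i: str) -> NodeRef:
    return NodeRef(ADR, i)


def I(i: str) -> NodeRef:
    return NodeRef(INDICATION, i)


def T(i: str) -> NodeRef:
    return NodeRef(TARGET, i)


@pytest.fixture
def tiny_graph() -> KnowledgeGraph:
    """One complete drug: d1 with one edge of each type."""
    g = KnowledgeGraph()
    g.add_edge(D("d1"), A("a1"))
    g.add_edge(D("d1"), T("t1"))
    g.add_edge(D("d1"), I("i1"))
    return g


@pytest.fixture
def toy_graph() -> KnowledgeGraph:
    """Fourteen drugs; a1 has 4 known causes, 3 of which share target t1,
    and exactly 1 of the 10 other drugs has t1: contingency (3, 1, 1, 9)."""
    g = KnowledgeGraph()
    causes = [D(f"c{i}") for i in range(4)]
    others = [D(f"o{i}") for i in range(10)]
    for d in causes:
        g.add_edge(d, A("a1"))
    for d in causes[:3]:
        g.add_edge(d, T("t1"))
    g.add_edge(others[0], T("t1"))
    for d in causes + others:  # make every drug complete
        g.add_edge(d, A("a_common"))
        g.add_edge(d, T("t_common"))
        g.add_edge(d, I("i_common"))
    return g


@pytest.fixture(scope="session")
def strong_graph():
    """Default strong-signal synthetic condition, fixed seed."""
    return generate_graph(PlantedSpec(seed=7))


@pytest.fixture(scope="session")
def strong_predictors(strong_graph):
    g, truth = strong_graph
    ps = select_predictors(g, truth.target_adr)
    assert not isinstance(ps, type(None))
    return ps


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
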