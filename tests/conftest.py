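import pytest

from homreason import build_demo, build_general_scenario, compile_assertions


@pytest.fixture(scope="session")
def demo():
    return build_demo()


@pytest.fixture(scope="session")
def demo_groups(demo):
    _, groups = compile_assertions(demo.assertions, "ava")
    return groups


@pytest.fixture(scope="session")
def scenario():
    return build_general_scenario()


def label_set(graph, ids):
    """Map a set of term ids to their display labels (test readability)."""
    return {graph.term(i).label for i in ids}
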