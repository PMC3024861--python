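import pytest

from treegram import fixtures


@pytest.fixture
def fig5():
    """6-vertex example tree: root with a-, c-, b-edges; the c-child again
    carries an a-edge and a b-edge."""
    return fixtures.fig5()


@pytest.fixture
def single_edge():
    from treegram import LabeledTree

    return LabeledTree.from_edges([(1, 2, "a")])


@pytest.fixture
def path3():
    """3-vertex path, both edges labeled a."""
    return fixtures.type_a(3)
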