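import pytest

from gallhist import enumerate_galled, single_gall_example, three_gall_example


@pytest.fixture(scope="session")
def single_gall():
    """11-leaf tree, one gall: N=1 left, M=2 right side nodes."""
    return single_gall_example()


@pytest.fixture(scope="session")
def three_gall():
    """17-leaf tree with three galls; 23,783,760 labeled histories."""
    return three_gall_example()


@pytest.fixture(scope="session")
def all_trees_to_6():
    """Every unlabeled galled tree with at most 6 leaves (102 trees)."""
    return [t for n in range(1, 7) for t in enumerate_galled(n)]
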