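import hypothesis
import numpy as np
import pytest

from cldnet import parse_edge_tables, table1_fixture

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def chain():
    """A -> B -> C."""
    return parse_edge_tables(
        [("A", "B", "+"), ("B", "C", "+")],
        [("A", "brain"), ("B", "physical"), ("C", "psychosocial")])


@pytest.fixture
def diamond():
    """A -> {B, C} -> D: two parallel shortest A->D paths."""
    return parse_edge_tables(
        [("A", "B", "+"), ("A", "C", "+"), ("B", "D", "+"), ("C", "D", "-")],
        [(v, "brain") for v in "ABCD"])


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
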