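from pathlib import Path

import networkx as nx
import pytest

from pdmg import SeedSet

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"


@pytest.fixture(scope="session")
def toy_dir() -> Path:
    return EXAMPLES / "toy"


@pytest.fixture(scope="session")
def t2d_seed_file() -> Path:
    return EXAMPLES / "t2d_seeds.txt"


@pytest.fixture
def star_graph() -> nx.Graph:
    """Five-node star: hub H with leaves L1..L4."""
    g = nx.Graph()
    g.add_edges_from([("H", f"L{i}") for i in range(1, 5)])
    return g


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A")])
    return g


@pytest.fixture
def single_seed() -> SeedSet:
    return SeedSet(frozenset({"HUB"}), "toy")


def graph_from_pairs(pairs) -> nx.Graph:
    """Build a simple graph from (u, v) pairs, dropping self-loops."""
    g = nx.Graph()
    g.add_edges_from((u, v) for u, v in pairs if u != v)
    return g
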