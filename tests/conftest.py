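import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from netctrl import MetaboliteNetwork, fixture_gallery


@pytest.fixture(scope="session")
def gallery():
    return fixture_gallery()


@pytest.fixture
def path3(gallery):
    return gallery["path3"]


@pytest.fixture
def star4(gallery):
    return gallery["star4"]


@pytest.fixture
def cycle3(gallery):
    return gallery["cycle3"]


@pytest.fixture
def fig1(gallery):
    return gallery["fig1"]


@pytest.fixture
def two_cliques(gallery):
    return gallery["two_cliques"]


def random_digraph(rng: np.random.Generator, n_max: int = 10, p: float = 0.25):
    """Small random directed simple graph (no self-loops) for oracle
    comparisons; keeps edge counts low enough for exhaustive enumeration."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"v{i}" for i in range(n)]
    net = MetaboliteNetwork()
    for v in nodes:
        net.add_node(v)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                net.add_link(nodes[i], nodes[j])
    return net
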