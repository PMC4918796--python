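import numpy as np
import pandas as pd
import pytest

from fluvidiv.network import Reach, RiverNetwork, SamplingSite
from fluvidiv.otu_io import OTUTable


@pytest.fixture
def y_network():
    """Two springs A, B joining at J, then J -> X (lengths 2, 4, 6; areas 10, 20, 30)."""
    return RiverNetwork(
        [
            Reach("r1", "A", "J", 2.0, 10.0),
            Reach("r2", "B", "J", 4.0, 20.0),
            Reach("r3", "J", "X", 6.0, 30.0),
        ]
    )


@pytest.fixture
def caterpillar_network():
    """S1->J1 (1), S2->J1 (3), J1->J2 (2), S3->J2 (4), J2->X (5)."""
    return RiverNetwork(
        [
            Reach("r1", "S1", "J1", 1.0, 0.0),
            Reach("r2", "S2", "J1", 3.0, 0.0),
            Reach("r3", "J1", "J2", 2.0, 0.0),
            Reach("r4", "S3", "J2", 4.0, 0.0),
            Reach("r5", "J2", "X", 5.0, 0.0),
        ]
    )


@pytest.fixture
def site_x():
    return SamplingSite("site", "X")


def random_tree(rng: np.random.Generator, max_reaches: int = 50) -> RiverNetwork:
    """Random rooted tree: each new reach attaches upstream of an existing node."""
    n_reaches = int(rng.integers(1, max_reaches + 1))
    nodes = ["n0"]
    reaches = []
    for i in range(n_reaches):
        child = f"n{i + 1}"
        parent = nodes[int(rng.integers(0, len(nodes)))]
        reaches.append(
            Reach(
                f"r{i}",
                child,
                parent,
                float(rng.uniform(0.1, 10.0)),
                float(rng.uniform(0.0, 5.0)),
            )
        )
        nodes.append(child)
    return RiverNetwork(reaches)


def enumerate_paths(network: RiverNetwork, node: str) -> list[list[Reach]]:
    """Brute-force oracle: every spring-to-node reach path, by explicit recursion."""
    ups = network.upstream_reaches_of(node)
    if not ups:
        return [[]]
    paths = []
    for r in ups:
        for sub in enumerate_paths(network, r.from_node):
            paths.append(sub + [r])
    return paths


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[5, 0, 2, 1], [0, 3, 2, 0], [1, 1, 0, 4]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )
    return OTUTable(counts)


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "site_id": ["a", "b", "c"],
            "fraction": ["FL", "FL", "PA"],
            "system": ["mainstem", "mainstem", "tributary"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
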