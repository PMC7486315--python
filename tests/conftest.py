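import random

import pytest

from arenosae import datasets
from arenosae.delimit import UltrametricTree, _Node


@pytest.fixture(scope="session")
def ontology():
    return datasets.load_base_ontology()


@pytest.fixture(scope="session")
def template():
    return datasets.load_section_template()


@pytest.fixture(scope="session")
def section():
    return datasets.load_section_description()


@pytest.fixture(scope="session")
def descriptions():
    """All terminal taxa, expanded with the section elements."""
    return datasets.load_all_descriptions()


@pytest.fixture(scope="session")
def stored_descriptions():
    """The redundancy-free stored form of each terminal description."""
    return datasets.load_all_descriptions(expanded=False)


@pytest.fixture(scope="session")
def key():
    return datasets.load_key()


def random_ultrametric(rng: random.Random, n_tips: int,
                       max_height: float = 1.0) -> UltrametricTree:
    """Random ultrametric tree via sequential joins at ascending heights."""
    nodes = [_Node(height=0.0, label=f"t{i:02d}") for i in range(n_tips)]
    heights = sorted(rng.uniform(0.0, max_height) for _ in range(n_tips - 1))
    for h in heights:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        merged = _Node(height=h, children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return UltrametricTree(nodes[0])
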