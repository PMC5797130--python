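"""Shared fixtures: small deterministic instances and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from lexiviable import MultiplexNetwork, generate_multiplex, reference_fixture
from lexiviable.synth import SyntheticConfig


def random_multiplex(
    rng: np.random.Generator,
    n_nodes: int = 10,
    n_layers: int = 2,
    p: float = 0.3,
) -> MultiplexNetwork:
    """Independent Bernoulli(p) layers over a shared node set."""
    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    edges = {}
    for layer in range(n_layers):
        pairs = [
            (nodes[i], nodes[j])
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
            if rng.random() < p
        ]
        if not pairs:  # keep every layer non-empty
            i, j = sorted(rng.choice(n_nodes, size=2, replace=False))
            pairs = [(nodes[i], nodes[j])]
        edges[f"L{layer}"] = pairs
    return MultiplexNetwork.from_edges(edges, nodes=nodes, allow_isolated=True)


@pytest.fixture(scope="session")
def fixture_instance():
    """The shipped deterministic N=60 / 2-layer instance."""
    return reference_fixture(seed=0)


@pytest.fixture(scope="session")
def reference_instance():
    """One reference-configuration synthetic lexicon (N=2000, 4 layers)."""
    return generate_multiplex(seed=0)


#: Small, fast 2-layer planted-core conditions for null-model experiments:
#: a dense viable core whose viability rests on inter-layer alignment.
TWO_LAYER_CONFIG = SyntheticConfig(
    n_words=300,
    n_layers=2,
    n_core=40,
    p_core=0.25,
    p_boundary=0.004,
    p_periphery=0.001,
    n_connector=0,
    stub_scale=0.2,
)


@pytest.fixture(scope="session")
def two_layer_instance():
    return generate_multiplex(TWO_LAYER_CONFIG, seed=0)
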