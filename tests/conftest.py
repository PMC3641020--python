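from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from ppinet.graph_model import InteractionTable
from ppinet.synthetic_data import SyntheticConfig, generate_interactome, generate_seed_list


def graph(edges, nodes=(), seeds=()):
    """Shorthand: build a seed-flagged graph from edge pairs."""
    g = nx.Graph()
    seeds = set(seeds)
    for n in nodes:
        g.add_node(n)
    g.add_edges_from(edges)
    for n in g.nodes:
        g.nodes[n]["seed"] = n in seeds
    return g


def table(*rows):
    """Shorthand: interaction table from (a, b, score) triples, cleaned."""
    return InteractionTable([(a, b, float(s)) for a, b, s in rows]).cleaned()


@pytest.fixture
def path3():
    return graph([("A", "B"), ("B", "C")])


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-bridge interactome shared across tests."""
    cfg = SyntheticConfig(n_background=110, n_modules=3, module_size=14,
                          n_seeds=28, seed_in_giant_fraction=26 / 28,
                          rng_seed=7)
    interactions, truth = generate_interactome(cfg)
    seeds = generate_seed_list(cfg, truth)
    return cfg, interactions, truth, seeds
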