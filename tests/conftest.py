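from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seednet import synthetic as sm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_connected_graph(rng: np.random.Generator, n_min=4, n_max=12) -> nx.Graph:
    """A random connected simple graph with string node labels."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        p = float(rng.uniform(0.25, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})


@pytest.fixture(scope="session")
def small_config() -> sm.SyntheticConfig:
    """Desk-scale synthetic study used by fast unit tests."""
    return sm.SyntheticConfig(
        n_background=400, attach_m=3, n_seeds=40, map_fraction=0.8,
        module_density=0.3, n_terms=30, term_size_range=(15, 50),
        n_planted_terms=3, planted_odds=20.0, rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> sm.SyntheticBundle:
    return sm.generate_bundle(small_config)


@pytest.fixture(scope="session")
def study_config() -> sm.SyntheticConfig:
    """The full study conditions (defaults), pinned to one seed."""
    return sm.SyntheticConfig(rng_seed=1)


@pytest.fixture(scope="session")
def study_bundle(study_config) -> sm.SyntheticBundle:
    return sm.generate_bundle(study_config)
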