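import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from disnet.dataset_builder import build_dataset
from disnet.graph_model import DiseaseAnnotation
from disnet.synthetic_data import generate_scenario


@pytest.fixture
def path_graph():
    return nx.path_graph(["A", "B", "C", "D"])


@pytest.fixture
def star_graph():
    g = nx.Graph()
    g.add_edges_from([("hub", f"leaf{i}") for i in range(4)])
    return g


@pytest.fixture
def toy_annotation():
    ann = DiseaseAnnotation()
    ann.add("B", "D1", "disease one", ["111"])
    ann.add("C", "D1", "disease one", ["222"])
    ann.add("C", "D2", "disease two", ["333"])
    return ann


def random_graphs(n_graphs=50, max_nodes=25, seed=0):
    """Small random graphs of mixed density, some disconnected."""
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n_graphs):
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.08, 0.5))
        graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return graphs


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small structured scenario for fast end-to-end tests."""
    from disnet.synthetic_data import ScenarioConfig

    config = ScenarioConfig(
        n_nodes=300, n_diseases=15, module_walk_length=8, noise_fraction=0.1, seed=11
    )
    return generate_scenario(config)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scenario):
    return build_dataset(tiny_scenario.net, tiny_scenario.annotation)


# --- shared paperlike/hidden fixtures for the acceptance suite -------------
# (expensive; computed once per session and reused across criteria checks)

@pytest.fixture(scope="session")
def paperlike_runs():
    """Feature-labeled datasets for the paperlike scenario over 10 seeds."""
    runs = []
    for seed in range(10):
        scenario = generate_scenario("paperlike", seed=seed)
        runs.append((seed, scenario, build_dataset(scenario.net, scenario.annotation)))
    return runs


@pytest.fixture(scope="session")
def hidden_runs():
    runs = []
    for seed in range(10):
        scenario = generate_scenario("hidden_genes", seed=seed)
        runs.append((seed, scenario, build_dataset(scenario.net, scenario.annotation)))
    return runs
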