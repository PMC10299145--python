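import networkx as nx
import pytest

import coexreg as cr


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic counts + truth + design (seed 0)."""
    cfg = cr.SyntheticConfig(seed=0)
    counts, truth = cr.generate_count_matrix(cfg)
    design, indicator = cr.generate_stage_design(cfg)
    return cfg, counts, truth, design, indicator


@pytest.fixture(scope="session")
def default_expr(default_dataset):
    """Filtered, normalised, log-transformed expression for the default dataset."""
    _, counts, truth, _, _ = default_dataset
    filtered, _ = cr.filter_low_counts(counts)
    expr = cr.vst_transform(filtered, cr.estimate_size_factors(filtered))
    return expr, truth


@pytest.fixture(scope="session")
def default_network():
    """Default planted-clique interaction network (seed 0) as a graph."""
    cfg = cr.SyntheticNetworkConfig(seed=0)
    edges, labels, truth = cr.generate_interaction_network(cfg)
    graph = nx.Graph()
    graph.add_nodes_from(f"n{i:04d}" for i in range(1, cfg.n_nodes + 1))
    graph.add_edges_from(edges)
    return graph, set(labels), truth


def graph_from_edges(edges, n_nodes=None, prefix="n", width=4):
    graph = nx.Graph()
    if n_nodes is not None:
        graph.add_nodes_from(f"{prefix}{i:0{width}d}" for i in range(1, n_nodes + 1))
    graph.add_edges_from(edges)
    return graph
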