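import numpy as np
import pytest

import graphomics as go


@pytest.fixture(scope="session")
def small_network():
    return go.simulate_network(n_genes=20, n_mirnas=10, n_circrnas=5,
                               n_probes=20, targets_per_mirna=3,
                               sponges_per_circ=2, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_network):
    cfg = go.CohortConfig(class_sizes=(10, 15, 10), effect_size=1.5,
                          n_informative=3, seed=11)
    return go.simulate_cohort(small_network, cfg)


@pytest.fixture(scope="session")
def small_graph(small_cohort):
    return go.cohort_graph(small_cohort)


@pytest.fixture(scope="session")
def fitted_small(small_graph):
    cfg = go.TrainConfig(epochs=60, embedding_dim=32, seed=3)
    return go.MultiOmicsGNN(small_graph, config=cfg).fit()


def tiny_graph():
    """patient P0, P1 -- two mRNAs and one miRNA targeting the first mRNA."""
    g = go.HeteroGraph()
    p0 = g.add_node("patient", "P0")
    p1 = g.add_node("patient", "P1")
    g0 = g.add_node("mrna", "g0")
    g1 = g.add_node("mrna", "g1")
    m0 = g.add_node("mirna", "m0")
    g.add_edge(p0, g0, 0.5)
    g.add_edge(p0, g1, -1.0)
    g.add_edge(p1, g0, 1.5)
    g.add_edge(p1, g1, 0.25)
    g.add_edge(p0, m0, 2.0)
    g.add_edge(m0, g0, 1.0)
    return g
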