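import networkx as nx
import numpy as np
import pytest

import connectoctrl as cc


def adjacency(graph: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(graph)


def make_matrix(weights, modality="SC", group="control", labels=None):
    """Wrap a raw weight array as a ConnectivityMatrix with labels 1..n."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if labels is None:
        labels = cc.RoiLabelSet(tuple(range(1, n + 1)))
    return cc.ConnectivityMatrix(w, labels, modality, group)


def symmetric_weights(rng, n, density=0.6, positive=True):
    """A random symmetric weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.gamma(2.0, 1.0, len(iu[0])) if positive else rng.normal(size=len(iu[0]))
    mask = rng.random(len(iu[0])) < density
    w[iu] = np.where(mask, vals, 0.0)
    return w + w.T


@pytest.fixture(scope="session")
def default_config():
    return cc.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def study_set(default_config):
    return cc.generate_study_set(default_config)


@pytest.fixture(scope="session")
def atlas_small():
    """All non-isomorphic simple graphs with 1..6 nodes."""
    return [g for g in nx.graph_atlas_g() if 1 <= g.number_of_nodes() <= 6]
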