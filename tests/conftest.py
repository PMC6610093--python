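import numpy as np
import pytest

import eegmst as em
from eegmst.montage import CHANNELS_19


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star19():
    return em.make_reference_tree("star", 19)


@pytest.fixture
def path19():
    return em.make_reference_tree("path", 19)


def spec_to_spanning_tree(spec, labels=None):
    """Turn a TreeSpec into a SpanningTree on electrode labels."""
    if labels is None:
        labels = list(CHANNELS_19)[: spec.n_nodes] if spec.n_nodes <= 19 \
            else [f"ch{k:02d}" for k in range(spec.n_nodes)]
    edges = [(labels[i], labels[j], s)
             for (i, j), s in zip(spec.edges, spec.edge_strengths)]
    return em.SpanningTree(list(labels), edges)


@pytest.fixture
def random_pli_matrix(rng):
    """A random symmetric PLI-like matrix on the 19 scalp electrodes."""
    n = 19
    v = rng.uniform(0.05, 0.95, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return em.ConnectivityMatrix(v, list(CHANNELS_19))


@pytest.fixture
def table1_params():
    """Published group-level ex-Gaussian parameter triples (ms)."""
    return {
        "SZ": em.ExGaussianParams(990.44, 78.31, 673.93),
        "HC": em.ExGaussianParams(765.19, 90.81, 455.23),
    }
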