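import numpy as np
import pytest

from ctxppi.graphdata import MultiScaleGraph, init_protein_features, split_edges
from ctxppi.synthgen import SyntheticGraphSpec, gen_multiscale_graph


@pytest.fixture(scope="session")
def small_graph_bundle():
    """A small 3-context multi-scale graph shared across unit tests."""
    spec = SyntheticGraphSpec(
        n_contexts=3, proteins_per_context=40, shared_fraction=0.5,
        within_block_p=0.35, between_block_p=0.05, n_blocks=3, seed=11,
    )
    return gen_multiscale_graph(spec)


@pytest.fixture(scope="session")
def small_graph(small_graph_bundle):
    graph = MultiScaleGraph(
        contexts=small_graph_bundle.contexts,
        metagraph=small_graph_bundle.metagraph,
    )
    init_protein_features(graph, d_in=16, seed=3)
    return graph


@pytest.fixture(scope="session")
def small_split(small_graph):
    return split_edges(small_graph, seed=5)


def finite_difference(fn, arrays, eps=1e-6):
    """Central finite-difference gradients of scalar fn w.r.t. numpy arrays."""
    grads = []
    for arr in arrays:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            hi = fn()
            arr[idx] = orig - eps
            lo = fn()
            arr[idx] = orig
            g[idx] = (hi - lo) / (2 * eps)
            it.iternext()
        grads.append(g)
    return grads
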