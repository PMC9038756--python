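import numpy as np
import pytest

from axonhmm import (
    PhantomConfig,
    make_phantom,
    reconstruct,
)
from axonhmm.hmm_graph import State, TransitionGraph, TransitionParams


def make_state(sid, x1=(0, 0, 0), tau1=(1, 0, 0), x0=(0, 0, 0), tau0=(-1, 0, 0), fragment_id=None, sibling=None):
    """Minimal State for geometry tests: only the fields the op under test reads."""
    return State(
        id=sid,
        fragment_id=sid // 2 if fragment_id is None else fragment_id,
        x0=np.asarray(x0, float),
        x1=np.asarray(x1, float),
        tau0=np.asarray(tau0, float),
        tau1=np.asarray(tau1, float),
        sibling_id=sid ^ 1 if sibling is None else sibling,
    )


def random_graph(rng, n_states=8, edge_prob=0.5, max_w=5.0):
    """A random weighted trellis (abstract states, no geometry) for path tests."""
    states = [make_state(i) for i in range(n_states)]
    edges = {}
    for i in range(n_states):
        for j in range(n_states):
            if i != j and rng.random() < edge_prob:
                w = float(rng.random() * max_w)
                edges[(i, j)] = {"U": 0.0, "log_prior": 0.0, "log_like": w, "weight": w}
    return TransitionGraph(states=states, edges=edges, params=TransitionParams())


@pytest.fixture(scope="session")
def dropout_phantom():
    """The gap-bridging study phantom: 100 um isolated tube, three 5 um gaps."""
    cfg = PhantomConfig(seed=7, dropout=[(30.0, 5.0), (55.0, 5.0), (75.0, 5.0)])
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def dropout_reconstruction(dropout_phantom):
    ph = dropout_phantom
    return reconstruct(
        ph.image,
        ph.prob_map,
        ph.gt_curves[0].points[0],
        ph.gt_curves[0].points[-1],
        seed=1,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A short clean tube on a small grid, for fast fragment/graph tests."""
    cfg = PhantomConfig(shape=(160, 64, 40), curve_length=40.0, seed=11)
    return make_phantom(cfg)
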