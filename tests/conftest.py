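import numpy as np
import pytest

from wmcpm import synth
from wmcpm.core import ConnectivityMatrix, NetworkMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_z_matrix(rng, n_nodes: int, subject: str = "sub-001") -> ConnectivityMatrix:
    """Random symmetric zero-diagonal z-scale matrix."""
    values = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    values[iu] = rng.normal(0.0, 0.4, size=len(iu[0]))
    values += values.T
    return ConnectivityMatrix(
        values=values, scale="z", node_ids=tuple(range(1, n_nodes + 1)), subject=subject
    )


def random_mask(rng, n_nodes: int, n_edges: int, polarity: str = "high") -> NetworkMask:
    pairs = [(i, j) for i in range(1, n_nodes + 1) for j in range(i + 1, n_nodes + 1)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    return NetworkMask(
        edges=frozenset(pairs[k] for k in chosen), polarity=polarity, atlas_size=n_nodes
    )


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small file-based synthetic study shared across pipeline tests."""
    root = tmp_path_factory.mktemp("study")
    config = synth.SimulationConfig(
        n_subjects=10,
        n_nodes=30,
        n_timepoints=100,
        n_high_edges=40,
        n_low_edges=30,
        spike_rate=0.01,
        seed=11,
    )
    from wmcpm.pipeline import simulate_study

    truth = simulate_study(config, root)
    return {"root": root, "config": config, "truth": truth}
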