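import numpy as np
import pytest

from logictrain.fixtures import ToySpec, toy_data, toy_truth
from logictrain.formats import MidasDataset, PriorKnowledgeNetwork
from logictrain.preprocess import expand, mark_status


@pytest.fixture(scope="session")
def toy():
    """Toy ground truth + simulated dataset (seed 0), shared across tests."""
    truth = toy_truth()
    data = toy_data(ToySpec(seed=0), truth)
    return truth, data


@pytest.fixture
def cascade():
    """EGF -> SOS -> ERK chain with SOS inhibitable, ERK measured."""
    net = PriorKnowledgeNetwork.from_edges(
        [("EGF", 1, "SOS"), ("SOS", 1, "ERK")]
    )
    data = MidasDataset(
        stimuli=["EGF"], inhibitors=["SOS"], signals=["ERK"],
        times=np.array([0.0, 10.0]),
        treatments=np.array([[1.0, 0.0], [1.0, 1.0]]),
        values=np.array([[[0.0, 1.0]], [[0.0, 0.0]]]),
    )
    scaffold = expand(net)
    status = mark_status(net, data)
    return scaffold, status, data


def random_layered_problem(rng, max_gates=12):
    """Random 3-layer signed network + data simulated from a random
    sub-model; None when the scaffold falls outside the size window."""
    from logictrain.boolean_engine import simulate_all

    n_mid = int(rng.integers(2, 4))
    layers = [["S1", "S2"], [f"M{i}" for i in range(n_mid)], ["R1", "R2"]]
    nodes = [n for layer in layers for n in layer]
    edges = []
    for a, b in [(0, 1), (1, 2), (0, 2)]:
        for s in layers[a]:
            for t in layers[b]:
                if rng.random() < (0.7 if a + 1 == b else 0.25):
                    edges.append((s, 1 if rng.random() < 0.75 else -1, t))
    for t in layers[1] + layers[2]:
        if not any(e[2] == t for e in edges):
            edges.append((str(rng.choice(layers[0])), 1, t))
    net = PriorKnowledgeNetwork.from_edges(edges, extra_nodes=nodes)
    data = MidasDataset(
        stimuli=["S1", "S2"], inhibitors=[], signals=["R1", "R2"],
        times=np.array([0.0, 10.0]),
        treatments=np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float),
        values=np.zeros((4, 2, 2)),
    )
    scaffold = expand(net, max_and_arity=2)
    if not (3 <= scaffold.n_gates <= max_gates):
        return None
    status = mark_status(net, data)
    true_bits = (rng.random(scaffold.n_gates) < 0.4).astype(int)
    sim = simulate_all(scaffold, true_bits, data, status)
    pos = {n: i for i, n in enumerate(sim.nodes)}
    vals = sim.states[:, [pos["R1"], pos["R2"]]]
    data.values[:, :, 1] = np.nan_to_num(vals, nan=0.5)
    return scaffold, status, data, true_bits
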