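import numpy as np
import pytest

from connktst import BrainGraph, LabeledGraphDataset, Modality
from connktst.simulate import SimulationParams, simulate_dataset


def random_symmetric(rng, l, modality=Modality.STRUCTURAL, density=1.0):
    """Random valid adjacency matrix: symmetric, zero diagonal."""
    iu = np.triu_indices(l, k=1)
    if modality is Modality.STRUCTURAL:
        vals = rng.gamma(2.0, 30.0, size=len(iu[0]))
    else:
        vals = rng.uniform(-1, 1, size=len(iu[0]))
    if density < 1.0:
        vals = np.where(rng.random(len(vals)) < density, vals, 0.0)
    w = np.zeros((l, l))
    w[iu] = vals
    return w + w.T


def random_dataset(rng, l=6, n=8, modality=Modality.STRUCTURAL, density=1.0):
    labels = tuple(f"r{i}" for i in range(l))
    graphs = tuple(
        BrainGraph.from_matrix(
            labels,
            random_symmetric(rng, l, modality, density),
            modality,
            f"s{i}",
        )
        for i in range(n)
    )
    classes = tuple(["A"] * (n // 2) + ["B"] * (n - n // 2))
    return LabeledGraphDataset(graphs, classes, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_functional(rng):
    """Nonnegative functional weights, as after positive thresholding."""
    labels = tuple(f"r{i}" for i in range(6))
    graphs = []
    for i in range(8):
        w = np.abs(random_symmetric(rng, 6, Modality.FUNCTIONAL))
        graphs.append(
            BrainGraph.from_matrix(labels, w, Modality.FUNCTIONAL, f"f{i}")
        )
    return LabeledGraphDataset(
        tuple(graphs), ("A",) * 4 + ("B",) * 4, labels
    )


@pytest.fixture(scope="session")
def default_design_study():
    """One simulated study at the emulated design: 50 nodes, 8+8 / 10+10."""
    return simulate_dataset(SimulationParams(seed=7))
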