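import numpy as np
import pytest

from meridiangcn.chem_io import MolGraph, smiles_to_graph
from meridiangcn.graph_net import GCNConfig, init_params
from meridiangcn.synthetic_data import SynthSpec, generate_dataset, random_molgraphs


def make_graph(features, neighbors) -> MolGraph:
    """Hand-built graph for layer-level tests (no chemistry involved)."""
    features = np.asarray(features, dtype=float)
    return MolGraph(
        atom_features=features,
        neighbors=[list(nb) for nb in neighbors],
        degrees=np.array([len(nb) for nb in neighbors]),
        smiles="",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small single-task planted-motif dataset shared by training-level tests."""
    spec = SynthSpec(n_molecules=60, task_names=("planted",),
                     positive_fractions=(0.3,), motifs=("c1ccncc1",),
                     label_noise=0.0, seed=7)
    return generate_dataset(spec)


@pytest.fixture
def small_params():
    cfg = GCNConfig(feature_dim=8, num_tasks=3, depth=2, width=5, gather_dim=4)
    return init_params(cfg, np.random.default_rng(0))
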