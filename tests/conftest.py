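import numpy as np
import pytest

from gcrnn import cpi_model
from gcrnn.cpi_model import ModelConfig
from gcrnn.mol_graph import Atom, MolecularGraph
from gcrnn.train_eval import build_vocabulary

TINY_PAIRS = [
    ("CC(=O)O", "MTEYKLVVHKWWHAGGAACDEF", 1),
    ("CCO", "MTEYKLVVAGGAACDEFGHIKL", 0),
    ("CC(C)N", "ACDEFGHIKLMNPQRSTVWYAC", 0),
]


def tiny_config(cell: str) -> ModelConfig:
    return ModelConfig(cell=cell, mol_dim=3, gnn_layers=3, embed_dim=4,
                       conv_layers=2, kernels=4, conv_window=3,
                       pool_window=3, pool_stride=3, rnn_hidden=3,
                       rnn_layers=2, rnn_out=3)


@pytest.fixture(scope="session")
def tiny_vocab():
    return build_vocabulary(TINY_PAIRS, radius=2)


@pytest.fixture
def tiny_model(tiny_vocab):
    def make(cell="gru", seed=0):
        return cpi_model.init_model(tiny_config(cell), tiny_vocab, seed=seed)
    return make


def random_graph(rng: np.random.Generator, max_atoms: int = 8) -> MolecularGraph:
    """Random connected graph with molecule-like labels (not valence-checked:
    these exercise the graph algorithms, not the SMILES parser)."""
    n = int(rng.integers(1, max_atoms + 1))
    symbols = rng.choice(["C", "N", "O", "S"], size=n)
    atoms = [Atom(str(s), bool(rng.random() < 0.2)) for s in symbols]
    bonds = []
    for j in range(1, n):  # random spanning tree keeps the graph connected
        i = int(rng.integers(0, j))
        bt = str(rng.choice(["single", "double", "triple", "aromatic"]))
        bonds.append((i, j, bt))
    existing = {(i, j) for i, j, _ in bonds}
    for _ in range(int(rng.integers(0, 3))):  # a few extra (cycle) edges
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist()) if n > 1 else (0, 0)
        if n > 1 and (i, j) not in existing:
            existing.add((i, j))
            bonds.append((int(i), int(j), str(rng.choice(["single", "aromatic"]))))
    bonds.sort()
    return MolecularGraph(atoms=atoms, bonds=bonds)
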