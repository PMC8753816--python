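"""Graph neural network over fingerprinted molecules.

Each r-radius node and edge fingerprint id owns a learned embedding row.
One transition layer updates, simultaneously from the time-t states,

    n_i <- sigmoid(n_i + sum_{j in S(i)} p_ij),   p_ij = ReLU(W_neighbor [n_j; e_ij] + b_neighbor)
    e_ij <- sigmoid(e_ij + q_ij),                 q_ij = ReLU(W_side (n_i + n_j) + b_side)

where S(i) is the set of direct neighbors of atom i.  After T layers the
molecule vector is the arithmetic mean of the node states, so its width d
never depends on molecule size and the embedding is invariant to atom
reindexing.

The sigmoid squashing of the residual update is deliberate: it keeps every
state coordinate strictly inside (0, 1) after each layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .mol_graph import FingerprintedGraph, MolecularGraph

DEFAULT_LAYERS = 3  # three-layer GNN paired with radius-2 fingerprints
INIT_SCALE = 0.1    # embeddings and weights start uniform on [-0.1, 0.1]


@dataclass
class GNNLayerParams:
    """One transition layer.  Weights are stored row-vector style, i.e.
    ``W_neighbor``: (2d, d) applied as [n_j; e_ij] @ W, ``W_side``: (d, d)."""

    W_neighbor: Tensor
    b_neighbor: Tensor
    W_side: Tensor
    b_side: Tensor


@dataclass
class GNNParams:
    node_embed: Tensor   # (node vocab, d), row 0 = UNK
    edge_embed: Tensor   # (edge vocab, d)
    layers: list[GNNLayerParams]
    d: int

    @property
    def T(self) -> int:
        return len(self.layers)

    def named_tensors(self):
        yield "gnn.node_embed", self.node_embed
        yield "gnn.edge_embed", self.edge_embed
        for t, lyr in enumerate(self.layers):
            yield f"gnn.layer{t}.W_neighbor", lyr.W_neighbor
            yield f"gnn.layer{t}.b_neighbor", lyr.b_neighbor
            yield f"gnn.layer{t}.W_side", lyr.W_side
            yield f"gnn.layer{t}.b_side", lyr.b_side


def init_gnn(node_vocab_size: int, edge_vocab_size: int, d: int,
             T: int = DEFAULT_LAYERS, seed: int = 0) -> GNNParams:
    """Randomly initialized GNN parameters, reproducible for a fixed seed."""
    if min(node_vocab_size, edge_vocab_size, d, T) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)

    def u(*shape):
        return ad.parameter(rng.uniform(-INIT_SCALE, INIT_SCALE, shape))

    layers = [GNNLayerParams(W_neighbor=u(2 * d, d), b_neighbor=u(d),
                             W_side=u(d, d), b_side=u(d))
              for _ in range(T)]
    return GNNParams(node_embed=u(node_vocab_size, d),
                     edge_embed=u(edge_vocab_size, d),
                     layers=layers, d=d)


class GraphIndex:
    """Precomputed index arrays for vectorized message passing.

    Directed view of the undirected bond list: every bond (i, j) contributes
    a message j->i and a message i->j.
    """

    def __init__(self, graph: MolecularGraph):
        dst, src, bond = [], [], []
        bi, bj = [], []
        for b, (i, j, _) in enumerate(graph.bonds):
            dst += [i, j]
            src += [j, i]
            bond += [b, b]
            bi.append(i)
            bj.append(j)
        self.n_atoms = graph.n_atoms
        self.msg_dst = np.asarray(dst, dtype=np.intp)
        self.msg_src = np.asarray(src, dtype=np.intp)
        self.msg_bond = np.asarray(bond, dtype=np.intp)
        self.bond_i = np.asarray(bi, dtype=np.intp)
        self.bond_j = np.asarray(bj, dtype=np.intp)


def node_update(node_vecs: Tensor, edge_vecs: Tensor, index: GraphIndex,
                layer: GNNLayerParams) -> Tensor:
    """n_i <- sigmoid(n_i + sum over neighbors of ReLU(W [n_j; e_ij] + b)).

    Atoms with no neighbors receive a zero message, i.e. sigmoid(n_i).
    """
    if index.msg_dst.size == 0:
        return ad.sigmoid(node_vecs)
    n_j = ad.take(node_vecs, index.msg_src)
    e_ij = ad.take(edge_vecs, index.msg_bond)
    pre = ad.add(ad.matmul(ad.concat([n_j, e_ij], axis=1), layer.W_neighbor),
                 layer.b_neighbor)
    p = ad.relu(pre)
    agg = ad.segment_sum(p, index.msg_dst, index.n_atoms)
    return ad.sigmoid(ad.add(node_vecs, agg))


def edge_update(node_vecs: Tensor, edge_vecs: Tensor, index: GraphIndex,
                layer: GNNLayerParams) -> Tensor:
    """e_ij <- sigmoid(e_ij + ReLU(W_side (n_i + n_j) + b_side)).

    Symmetric in the endpoints because it acts on n_i + n_j; reads the same
    time-t node states node_update reads.
    """
    if index.bond_i.size == 0:
        return edge_vecs
    n_i = ad.take(node_vecs, index.bond_i)
    n_j = ad.take(node_vecs, index.bond_j)
    q = ad.relu(ad.add(ad.matmul(ad.add(n_i, n_j), layer.W_side), layer.b_side))
    return ad.sigmoid(ad.add(edge_vecs, q))


def embed_molecule(fpg: FingerprintedGraph, params: GNNParams,
                   index: GraphIndex | None = None) -> Tensor:
    """Run T transition layers and return the mean node state, shape (1, d)."""
    if fpg.graph.n_atoms == 0:
        raise ValueError("cannot embed an empty molecular graph")
    if index is None:
        index = GraphIndex(fpg.graph)
    nodes = ad.take(params.node_embed, np.asarray(fpg.node_ids, dtype=np.intp))
    edges = ad.take(params.edge_embed, np.asarray(fpg.edge_ids, dtype=np.intp))
    for layer in params.layers:
        new_nodes = node_update(nodes, edges, index, layer)
        new_edges = edge_update(nodes, edges, index, layer)
        nodes, edges = new_nodes, new_edges
    return ad.mean_rows(nodes)
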