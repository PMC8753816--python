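"""GNN transition layers: oracle equivalence, ranges, permutation invariance."""

import numpy as np
import pytest

from gcrnn import autodiff as ad
from gcrnn import compound_gnn
from gcrnn.compound_gnn import (GraphIndex, edge_update, embed_molecule,
                                init_gnn, node_update)
from gcrnn.mol_graph import (FingerprintedGraph, SubgraphVocabulary,
                             assign_fingerprints)

from conftest import random_graph


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _naive_node_update(nodes, edges, graph, layer):
    """Per-node Python-loop oracle for the node transition."""
    W, b = layer.W_neighbor.data, layer.b_neighbor.data
    out = np.empty_like(nodes)
    for i in range(graph.n_atoms):
        total = np.zeros(nodes.shape[1])
        for j, bidx in graph.adjacency[i]:
            msg = np.concatenate([nodes[j], edges[bidx]]) @ W + b
            total += np.maximum(msg, 0.0)
        out[i] = _sigmoid(nodes[i] + total)
    return out


def _naive_edge_update(nodes, edges, graph, layer):
    W, b = layer.W_side.data, layer.b_side.data
    out = np.empty_like(edges)
    for bidx, (i, j, _) in enumerate(graph.bonds):
        q = np.maximum((nodes[i] + nodes[j]) @ W + b, 0.0)
        out[bidx] = _sigmoid(edges[bidx] + q)
    return out


def test_init_is_deterministic_and_shaped():
    a = init_gnn(5, 4, d=4, T=3, seed=123)
    b = init_gnn(5, 4, d=4, T=3, seed=123)
    for (na, ta), (nb, tb) in zip(a.named_tensors(), b.named_tensors()):
        assert na == nb
        np.testing.assert_array_equal(ta.data, tb.data)
    assert a.layers[0].W_neighbor.shape == (8, 4)  # [n_j; e_ij] doubles width
    assert len(a.layers) == 3
    assert np.all(np.abs(a.node_embed.data) <= 0.1)


def test_zero_weights_reduce_update_to_sigmoid_of_state():
    rng = np.random.default_rng(0)
    g = random_graph(rng)
    params = init_gnn(3, 3, d=2, T=1, seed=0)
    layer = params.layers[0]
    for t in (layer.W_neighbor, layer.b_neighbor, layer.W_side, layer.b_side):
        t.data[...] = 0.0
    nodes = rng.normal(size=(g.n_atoms, 2))
    edges = rng.normal(size=(max(g.n_bonds, 1), 2))[:g.n_bonds]
    idx = GraphIndex(g)
    out = node_update(ad.Tensor(nodes), ad.Tensor(edges), idx, layer)
    np.testing.assert_allclose(out.data, _sigmoid(nodes), atol=1e-15)
    # zero state as well: every entry sigmoid(0) = 0.5
    out0 = node_update(ad.Tensor(np.zeros_like(nodes)),
                       ad.Tensor(np.zeros_like(edges)), idx, layer)
    np.testing.assert_allclose(out0.data, 0.5, atol=1e-15)
    if g.n_bonds:
        eout0 = edge_update(ad.Tensor(np.zeros_like(nodes)),
                            ad.Tensor(np.zeros_like(edges)), idx, layer)
        np.testing.assert_allclose(eout0.data, 0.5, atol=1e-15)


def test_transitions_match_naive_loop_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        g = random_graph(rng)
        params = init_gnn(3, 3, d=2, T=1, seed=int(rng.integers(1 << 30)))
        layer = params.layers[0]
        nodes = rng.normal(size=(g.n_atoms, 2))
        edges = rng.normal(size=(g.n_bonds, 2))
        idx = GraphIndex(g)
        got = node_update(ad.Tensor(nodes), ad.Tensor(edges), idx, layer)
        np.testing.assert_allclose(
            got.data, _naive_node_update(nodes, edges, g, layer), atol=1e-12)
        if g.n_bonds:
            gote = edge_update(ad.Tensor(nodes), ad.Tensor(edges), idx, layer)
            np.testing.assert_allclose(
                gote.data, _naive_edge_update(nodes, edges, g, layer), atol=1e-12)


def test_edge_update_symmetric_in_endpoints():
    # q uses n_i + n_j, so swapping endpoint states leaves e' unchanged
    rng = np.random.default_rng(3)
    g = random_graph(rng)
    if not g.n_bonds:
        pytest.skip("drew an edgeless graph")
    params = init_gnn(3, 3, d=2, T=1, seed=1)
    nodes = rng.normal(size=(g.n_atoms, 2))
    edges = rng.normal(size=(g.n_bonds, 2))
    idx = GraphIndex(g)
    swapped = GraphIndex(g)
    swapped.bond_i, swapped.bond_j = swapped.bond_j, swapped.bond_i
    a = edge_update(ad.Tensor(nodes), ad.Tensor(edges), idx, params.layers[0])
    b = edge_update(ad.Tensor(nodes), ad.Tensor(edges), swapped, params.layers[0])
    np.testing.assert_allclose(a.data, b.data, atol=1e-15)


def _fingerprint(g, r=2):
    vocab = SubgraphVocabulary(radius=r)
    return assign_fingerprints(g, r, vocab, allow_grow=True), vocab


def test_states_stay_strictly_inside_unit_interval():
    rng = np.random.default_rng(9)
    for _ in range(10):
        g = random_graph(rng)
        fpg, vocab = _fingerprint(g)
        params = init_gnn(vocab.node_vocab_size, vocab.edge_vocab_size,
                          d=4, T=3, seed=0)
        idx = GraphIndex(g)
        nodes = ad.take(params.node_embed, np.asarray(fpg.node_ids))
        edges = ad.take(params.edge_embed, np.asarray(fpg.edge_ids))
        for layer in params.layers:
            new_nodes = node_update(nodes, edges, idx, layer)
            new_edges = edge_update(nodes, edges, idx, layer)
            nodes, edges = new_nodes, new_edges
            assert np.all((nodes.data > 0) & (nodes.data < 1))
            if g.n_bonds:
                assert np.all((edges.data > 0) & (edges.data < 1))


def test_embedding_invariant_to_atom_relabeling():
    rng = np.random.default_rng(13)
    for _ in range(20):
        g = random_graph(rng)
        vocab = SubgraphVocabulary(radius=2)
        fpg = assign_fingerprints(g, 2, vocab, allow_grow=True)
        params = init_gnn(vocab.node_vocab_size, vocab.edge_vocab_size,
                          d=4, T=3, seed=2)
        y = embed_molecule(fpg, params)
        perm = rng.permutation(g.n_atoms).tolist()
        gp = g.permuted(perm)
        fpg_p = assign_fingerprints(gp, 2, vocab, allow_grow=False)
        yp = embed_molecule(fpg_p, params)
        np.testing.assert_allclose(y.data, yp.data, atol=1e-12)


def test_embedding_width_fixed_and_empty_graph_rejected(tiny_vocab):
    from gcrnn.mol_graph import MolecularGraph, parse_smiles
    params = init_gnn(tiny_vocab.node_vocab_size, tiny_vocab.edge_vocab_size,
                      d=7, T=2, seed=0)
    for smiles in ("C", "CCO", "CC(=O)OCC"):
        fpg = assign_fingerprints(parse_smiles(smiles), 2, tiny_vocab)
        assert embed_molecule(fpg, params).shape == (1, 7)
    empty = FingerprintedGraph(
        graph=MolecularGraph(atoms=[], bonds=[]), node_ids=[], edge_ids=[])
    with pytest.raises(ValueError, match="empty"):
        embed_molecule(empty, params)


def test_single_atom_molecule_embeds_through_t_layers():
    # no neighbors: each layer squashes, mean of one vector is the vector
    vocab = SubgraphVocabulary(radius=2)
    from gcrnn.mol_graph import parse_smiles
    fpg = assign_fingerprints(parse_smiles("C"), 2, vocab, allow_grow=True)
    params = init_gnn(vocab.node_vocab_size, vocab.edge_vocab_size,
                      d=3, T=2, seed=0)
    y = embed_molecule(fpg, params)
    expected = params.node_embed.data[fpg.node_ids[0]]
    for _ in range(2):
        expected = _sigmoid(expected)
    np.testing.assert_allclose(y.data.ravel(), expected, atol=1e-14)
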