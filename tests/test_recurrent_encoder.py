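"""LSTM/GRU cells vs scalar-loop oracles; bidirectional fusion; readout."""

import numpy as np
import pytest

from gcrnn import autodiff as ad
from gcrnn.autodiff import Tensor
from gcrnn.recurrent_encoder import (bidirectional_encode,
                                     gru_step, init_birnn, lstm_step,
                                     protein_readout)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _naive_lstm_step(x, h, c, cell):
    """Scalar-loop oracle: one hidden unit at a time."""
    hdim = h.size
    z = np.concatenate([x.ravel(), h.ravel()])
    h_out, c_out = np.empty(hdim), np.empty(hdim)
    for u in range(hdim):
        i = _sigmoid(z @ cell.W_i.data[:, u] + cell.b_i.data[u])
        f = _sigmoid(z @ cell.W_f.data[:, u] + cell.b_f.data[u])
        o = _sigmoid(z @ cell.W_o.data[:, u] + cell.b_o.data[u])
        g = np.tanh(z @ cell.W_c.data[:, u] + cell.b_c.data[u])
        c_out[u] = f * c.ravel()[u] + i * g
        h_out[u] = o * np.tanh(c_out[u])
    return h_out, c_out


def _naive_gru_step(x, h, cell):
    hdim = h.size
    h_out = np.empty(hdim)
    z_in = np.concatenate([x.ravel(), h.ravel()])
    zg = _sigmoid(z_in @ cell.W_z.data + cell.b_z.data)
    rg = _sigmoid(z_in @ cell.W_r.data + cell.b_r.data)
    cand_in = np.concatenate([x.ravel(), rg * h.ravel()])
    for u in range(hdim):
        h_tilde = np.tanh(cand_in @ cell.W_h.data[:, u])
        h_out[u] = (1 - zg[u]) * h.ravel()[u] + zg[u] * h_tilde
    return h_out


def _cells(cell_type, in_dim=2, h=3, seed=0):
    return init_birnn(in_dim, hidden=h, out_dim=h, n_layers=1,
                      cell=cell_type, seed=seed).layers[0]


def test_lstm_zero_params_zero_state_gives_zero_output():
    layer = _cells("lstm")
    for _, t in layer.fwd.named_tensors("x"):
        t.data[...] = 0.0
    h, c = lstm_step(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 3))),
                     Tensor(np.zeros((1, 3))), layer.fwd)
    np.testing.assert_array_equal(h.data, 0.0)  # o*tanh(c)=0.5*tanh(0)
    np.testing.assert_array_equal(c.data, 0.0)


def test_lstm_gate_identities_preserve_memory():
    layer = _cells("lstm", seed=1)
    cell = layer.fwd
    # force f -> 1, i -> 0 via large biases: c_t must equal c_prev
    cell.W_i.data[...] = 0.0
    cell.W_f.data[...] = 0.0
    cell.b_i.data[...] = -50.0
    cell.b_f.data[...] = 50.0
    rng = np.random.default_rng(2)
    c_prev = rng.normal(size=(1, 3))
    _, c_t = lstm_step(Tensor(rng.normal(size=(1, 2))),
                       Tensor(rng.normal(size=(1, 3))),
                       Tensor(c_prev), cell)
    np.testing.assert_allclose(c_t.data, c_prev, atol=1e-12)


def test_gru_update_gate_closed_keeps_state():
    layer = _cells("gru", seed=3)
    cell = layer.fwd
    cell.W_z.data[...] = 0.0
    cell.b_z.data[...] = -50.0  # z -> 0: h_t = h_prev
    rng = np.random.default_rng(4)
    h_prev = rng.normal(size=(1, 3))
    h_t = gru_step(Tensor(rng.normal(size=(1, 2))), Tensor(h_prev), cell)
    np.testing.assert_allclose(h_t.data, h_prev, atol=1e-12)


def test_steps_match_scalar_loop_oracles():
    rng = np.random.default_rng(5)
    for trial in range(100):
        layer_l = _cells("lstm", seed=trial)
        layer_g = _cells("gru", seed=trial)
        x = rng.normal(size=(1, 2))
        h = rng.normal(size=(1, 3))
        c = rng.normal(size=(1, 3))
        got_h, got_c = lstm_step(Tensor(x), Tensor(h), Tensor(c), layer_l.fwd)
        ora_h, ora_c = _naive_lstm_step(x, h, c, layer_l.fwd)
        np.testing.assert_allclose(got_h.data.ravel(), ora_h, atol=1e-12)
        np.testing.assert_allclose(got_c.data.ravel(), ora_c, atol=1e-12)
        got = gru_step(Tensor(x), Tensor(h), layer_g.fwd)
        np.testing.assert_allclose(got.data.ravel(),
                                   _naive_gru_step(x, h, layer_g.fwd),
                                   atol=1e-12)


def test_gate_and_state_ranges():
    rng = np.random.default_rng(6)
    params = init_birnn(2, hidden=4, out_dim=4, n_layers=1, cell="lstm", seed=7)
    cell = params.layers[0].fwd
    h = Tensor(np.zeros((1, 4)))
    c = Tensor(np.zeros((1, 4)))
    for _ in range(10):
        h, c = lstm_step(Tensor(rng.normal(size=(1, 2))), h, c, cell)
        assert np.all((h.data > -1) & (h.data < 1))


@pytest.mark.parametrize("cell_type", ["lstm", "gru"])
def test_bidirectional_equals_two_unidirectional_passes(cell_type):
    """Compositional oracle built from the (independently verified) step
    functions: forward pass, backward pass, summed projections, one layer."""
    rng = np.random.default_rng(8)
    params = init_birnn(2, hidden=3, out_dim=3, n_layers=1,
                        cell=cell_type, seed=9)
    xs = rng.normal(size=(5, 2))
    got = bidirectional_encode(Tensor(xs), params)
    lyr = params.layers[0]

    def run(cell, seq):
        h = np.zeros((1, 3))
        c = np.zeros((1, 3))
        outs = []
        for t in range(len(seq)):
            if cell_type == "lstm":
                ht, ct = lstm_step(Tensor(seq[t:t + 1]), Tensor(h), Tensor(c), cell)
                h, c = ht.data, ct.data
            else:
                h = gru_step(Tensor(seq[t:t + 1]), Tensor(h), cell).data
            outs.append(h.copy())
        return np.vstack(outs)

    hf = run(lyr.fwd, xs)
    hb = run(lyr.bwd, xs[::-1])[::-1]
    expected = hf @ lyr.W_fwd.data + hb @ lyr.W_bwd.data
    np.testing.assert_allclose(got.data, expected, atol=1e-12)


def test_length_one_sequence_reads_same_input_both_ways():
    params = init_birnn(2, hidden=3, out_dim=3, n_layers=1, cell="gru", seed=10)
    lyr = params.layers[0]
    x = np.random.default_rng(11).normal(size=(1, 2))
    got = bidirectional_encode(Tensor(x), params)
    hf = gru_step(Tensor(x), Tensor(np.zeros((1, 3))), lyr.fwd).data
    hb = gru_step(Tensor(x), Tensor(np.zeros((1, 3))), lyr.bwd).data
    np.testing.assert_allclose(
        got.data, hf @ lyr.W_fwd.data + hb @ lyr.W_bwd.data, atol=1e-14)


def test_palindromic_input_with_mirrored_parameters_is_palindromic():
    params = init_birnn(2, hidden=3, out_dim=3, n_layers=2, cell="gru", seed=12)
    for lyr in params.layers:  # share the two directions
        lyr.bwd = lyr.fwd
        lyr.W_bwd = lyr.W_fwd
    rng = np.random.default_rng(13)
    half = rng.normal(size=(3, 2))
    xs = np.vstack([half, half[::-1]])
    out = bidirectional_encode(Tensor(xs), params).data
    np.testing.assert_allclose(out, out[::-1], atol=1e-12)


def test_readout_mean_and_errors():
    H = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]))
    np.testing.assert_array_equal(protein_readout(H).data, [[2.0, 3.0]])
    perm = Tensor(np.array([[3.0, 4.0], [1.0, 2.0]]))
    np.testing.assert_array_equal(protein_readout(perm).data, [[2.0, 3.0]])
    with pytest.raises(ValueError):
        bidirectional_encode(Tensor(np.zeros((0, 2))),
                             init_birnn(2, hidden=2, n_layers=1, cell="gru"))


def test_two_layer_stack_changes_output_and_keeps_width():
    rng = np.random.default_rng(14)
    xs = Tensor(rng.normal(size=(4, 2)))
    one = init_birnn(2, hidden=3, out_dim=3, n_layers=1, cell="lstm", seed=15)
    two = init_birnn(2, hidden=3, out_dim=3, n_layers=2, cell="lstm", seed=15)
    o1 = bidirectional_encode(xs, one)
    o2 = bidirectional_encode(xs, two)
    assert o1.shape == o2.shape == (4, 3)
    assert not np.allclose(o1.data, o2.data)
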