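"""Stacked bidirectional recurrent layers over the pooled protein features.

Each layer runs an independent forward (left-to-right) and backward
(right-to-left) pass of the chosen cell (LSTM or GRU) from zero initial
states, then fuses the two per-position hidden states with learned
projections:

    H_t = W_fwd h>_t + W_bwd h<_t.

Layer 2 consumes layer 1's fused outputs.  The protein vector is the
arithmetic mean of the final fused sequence, so its width is fixed no
matter how long the protein is.

Cell equations (per direction, weights independent):

LSTM:  i, f, o = sigmoid(W [x_t, h_{t-1}] + b);  g = tanh(W_c [x_t, h_{t-1}] + b_c)
       c_t = f * c_{t-1} + i * g;                h_t = o * tanh(c_t)
GRU:   z, r = sigmoid(W [x_t, h_{t-1}] + b)
       h~ = tanh(W_h [x_t, r * h_{t-1}])         (no bias on the candidate)
       h_t = (1 - z) * h_{t-1} + z * h~
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DEFAULT_HIDDEN = 320
DEFAULT_LAYERS = 2
INIT_SCALE = 0.1


@dataclass
class LSTMCellParams:
    """Gate weights, each (input + hidden, hidden); biases (hidden,)."""
    W_i: Tensor
    W_f: Tensor
    W_o: Tensor
    W_c: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_c: Tensor

    def named_tensors(self, prefix: str):
        for k in ("W_i", "W_f", "W_o", "W_c", "b_i", "b_f", "b_o", "b_c"):
            yield f"{prefix}.{k}", getattr(self, k)


@dataclass
class GRUCellParams:
    """Update/reset gate weights and candidate weight; no candidate bias."""
    W_z: Tensor
    W_r: Tensor
    W_h: Tensor
    b_z: Tensor
    b_r: Tensor

    def named_tensors(self, prefix: str):
        for k in ("W_z", "W_r", "W_h", "b_z", "b_r"):
            yield f"{prefix}.{k}", getattr(self, k)


@dataclass
class BiRNNLayerParams:
    fwd: LSTMCellParams | GRUCellParams
    bwd: LSTMCellParams | GRUCellParams
    W_fwd: Tensor  # (hidden, out) fusion projection, forward direction
    W_bwd: Tensor  # (hidden, out) fusion projection, backward direction

    def named_tensors(self, prefix: str):
        yield from self.fwd.named_tensors(f"{prefix}.fwd")
        yield from self.bwd.named_tensors(f"{prefix}.bwd")
        yield f"{prefix}.W_fwd", self.W_fwd
        yield f"{prefix}.W_bwd", self.W_bwd


@dataclass
class BiRNNParams:
    layers: list[BiRNNLayerParams]
    cell: str      # "lstm" or "gru"
    hidden: int
    out_dim: int

    def named_tensors(self):
        for t, lyr in enumerate(self.layers):
            yield from lyr.named_tensors(f"rnn.layer{t}")


def _init_cell(cell: str, in_dim: int, hidden: int, u) -> LSTMCellParams | GRUCellParams:
    w = in_dim + hidden
    if cell == "lstm":
        return LSTMCellParams(W_i=u(w, hidden), W_f=u(w, hidden),
                              W_o=u(w, hidden), W_c=u(w, hidden),
                              b_i=u(hidden), b_f=u(hidden),
                              b_o=u(hidden), b_c=u(hidden))
    if cell == "gru":
        return GRUCellParams(W_z=u(w, hidden), W_r=u(w, hidden),
                             W_h=u(w, hidden), b_z=u(hidden), b_r=u(hidden))
    raise ValueError(f"unknown cell type {cell!r}")


def init_birnn(input_dim: int, hidden: int = DEFAULT_HIDDEN,
               out_dim: int | None = None, n_layers: int = DEFAULT_LAYERS,
               cell: str = "lstm", seed: int = 0) -> BiRNNParams:
    """Independent forward/backward cells per layer plus fusion projections."""
    if out_dim is None:
        out_dim = hidden
    rng = np.random.default_rng(seed)

    def u(*shape):
        return ad.parameter(rng.uniform(-INIT_SCALE, INIT_SCALE, shape))

    layers = []
    in_dim = input_dim
    for _ in range(n_layers):
        layers.append(BiRNNLayerParams(
            fwd=_init_cell(cell, in_dim, hidden, u),
            bwd=_init_cell(cell, in_dim, hidden, u),
            W_fwd=u(hidden, out_dim), W_bwd=u(hidden, out_dim)))
        in_dim = out_dim
    return BiRNNParams(layers=layers, cell=cell, hidden=hidden, out_dim=out_dim)


def lstm_step(x_t: Tensor, h_prev: Tensor, c_prev: Tensor,
              cell: LSTMCellParams) -> tuple[Tensor, Tensor]:
    """One LSTM update; x_t (1, in), h_prev/c_prev (1, hidden)."""
    z = ad.concat([x_t, h_prev], axis=1)
    i = ad.sigmoid(ad.add(ad.matmul(z, cell.W_i), cell.b_i))
    f = ad.sigmoid(ad.add(ad.matmul(z, cell.W_f), cell.b_f))
    o = ad.sigmoid(ad.add(ad.matmul(z, cell.W_o), cell.b_o))
    g = ad.tanh(ad.add(ad.matmul(z, cell.W_c), cell.b_c))
    c_t = ad.add(ad.mul(f, c_prev), ad.mul(i, g))
    h_t = ad.mul(o, ad.tanh(c_t))
    return h_t, c_t


def gru_step(x_t: Tensor, h_prev: Tensor, cell: GRUCellParams) -> Tensor:
    """One GRU update; candidate has no bias by design."""
    z_in = ad.concat([x_t, h_prev], axis=1)
    z = ad.sigmoid(ad.add(ad.matmul(z_in, cell.W_z), cell.b_z))
    r = ad.sigmoid(ad.add(ad.matmul(z_in, cell.W_r), cell.b_r))
    h_tilde = ad.tanh(ad.matmul(ad.concat([x_t, ad.mul(r, h_prev)], axis=1),
                                cell.W_h))
    one_minus_z = ad.add(ad.scale(z, -1.0), 1.0)
    return ad.add(ad.mul(one_minus_z, h_prev), ad.mul(z, h_tilde))


def _run_direction(xs: Tensor, cell_params, cell: str, hidden: int,
                   reverse: bool) -> Tensor:
    """Unidirectional pass with zero initial state; returns (L, hidden)."""
    L = xs.shape[0]
    order = range(L - 1, -1, -1) if reverse else range(L)
    h = Tensor(np.zeros((1, hidden)))
    c = Tensor(np.zeros((1, hidden)))
    outs: list[Tensor] = [None] * L
    for t in order:
        x_t = ad.take(xs, np.asarray([t], dtype=np.intp))
        if cell == "lstm":
            h, c = lstm_step(x_t, h, c, cell_params)
        else:
            h = gru_step(x_t, h, cell_params)
        outs[t] = h
    return ad.concat(outs, axis=0)


def bidirectional_encode(xs: Tensor, params: BiRNNParams) -> Tensor:
    """Fused bidirectional outputs, stacked over layers; (L, out_dim)."""
    if xs.shape[0] == 0:
        raise ValueError("cannot encode an empty sequence")
    h = xs
    for lyr in params.layers:
        hf = _run_direction(h, lyr.fwd, params.cell, params.hidden, reverse=False)
        hb = _run_direction(h, lyr.bwd, params.cell, params.hidden, reverse=True)
        h = ad.add(ad.matmul(hf, lyr.W_fwd), ad.matmul(hb, lyr.W_bwd))
    return h


def protein_readout(H: Tensor) -> Tensor:
    """Arithmetic mean over positions, shape (1, out_dim)."""
    if H.shape[0] == 0:
        raise ValueError("cannot average an empty sequence")
    return ad.mean_rows(H)
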