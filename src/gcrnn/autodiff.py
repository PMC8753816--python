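"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine providing exactly the operations the model needs:
dense linear algebra, pointwise nonlinearities, row gather/scatter for
embedding tables and graph message passing, 1-D "same" convolution and
windowed max-pooling, and a fused softmax cross-entropy.  All arrays are
float64; gradients accumulate into ``Tensor.grad``.

Gradients produced here are checked against central finite differences in
the test suite, so every backward rule below has an independent numerical
oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "parameter", "add", "mul", "scale", "matmul", "relu",
    "sigmoid", "tanh", "concat", "sum_all", "mean_rows", "take",
    "segment_sum", "conv1d_same", "maxpool1d", "softmax_cross_entropy",
    "softmax",
]


class Tensor:
    """A NumPy array plus an optional place on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``seed`` given)."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar")
            seed = np.ones_like(self.data)
        self.grad = np.asarray(seed, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    return Tensor(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _from_op(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(p: Tensor, g: np.ndarray) -> None:
    if p.requires_grad:
        if p.grad is None:
            p.grad = np.zeros_like(p.data)
        p.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# Elementwise -------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _from_op(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _from_op(out_data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        _accum(a, g * s)

    return _from_op(a.data * s, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _from_op(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _from_op(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return _from_op(out_data, (a,), backward)


# Linear algebra ----------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _from_op(out_data, (a, b), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _from_op(out_data, tuple(tensors), backward)


def sum_all(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, np.full_like(a.data, float(g)))

    return _from_op(a.data.sum(), (a,), backward)


def mean_rows(a: Tensor) -> Tensor:
    """Mean over axis 0 of a 2-D tensor; returns shape (1, C)."""
    n = a.data.shape[0]
    out_data = a.data.mean(axis=0, keepdims=True)

    def backward(g):
        _accum(a, np.repeat(g / n, n, axis=0))

    return _from_op(out_data, (a,), backward)


# Gather / scatter --------------------------------------------------

def take(a: Tensor, indices) -> Tensor:
    """Row gather: out[i] = a[indices[i]]."""
    indices = np.asarray(indices, dtype=np.intp)
    out_data = a.data[indices]

    def backward(g):
        if a.requires_grad:
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            np.add.at(a.grad, indices, g)

    return _from_op(out_data, (a,), backward)


def segment_sum(a: Tensor, segment_ids, num_segments: int) -> Tensor:
    """out[s] = sum of rows of ``a`` with segment_ids == s (empty rows 0)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + a.data.shape[1:])
    np.add.at(out_data, segment_ids, a.data)

    def backward(g):
        _accum(a, g[segment_ids])

    return _from_op(out_data, (a,), backward)


# Convolution / pooling ---------------------------------------------

def conv1d_same(x: Tensor, w: Tensor) -> Tensor:
    """1-D convolution with "same" zero padding and no bias.

    ``x``: (L, C) positions x channels; ``w``: (K, M, C) kernels x window x
    channels.  out[i, k] = sum_{m,c} w[k, m, c] * x_padded[i + m, c].
    """
    L, C = x.data.shape
    K, M, Cw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    pl = (M - 1) // 2
    xp = np.zeros((L + M - 1, C))
    xp[pl:pl + L] = x.data
    out_data = np.zeros((L, K))
    for m in range(M):
        out_data += xp[m:m + L] @ w.data[:, m, :].T

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for m in range(M):
                dxp[m:m + L] += g @ w.data[:, m, :]
            _accum(x, dxp[pl:pl + L])
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for m in range(M):
                dw[:, m, :] = g.T @ xp[m:m + L]
            _accum(w, dw)

    return _from_op(out_data, (x, w), backward)


def maxpool1d(x: Tensor, window: int, stride: int) -> Tensor:
    """Windowed per-channel max over axis 0; the final partial window is
    kept (max over the remaining positions).  Output length ceil(L/stride)
    when stride == window."""
    L, C = x.data.shape
    starts = list(range(0, L, stride))
    out_data = np.empty((len(starts), C))
    arg = np.empty((len(starts), C), dtype=np.intp)
    for i, s in enumerate(starts):
        block = x.data[s:s + window]
        a = block.argmax(axis=0)
        arg[i] = a + s
        out_data[i] = block[a, np.arange(C)]

    def backward(g):
        if x.requires_grad:
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            cols = np.broadcast_to(np.arange(C), arg.shape)
            np.add.at(x.grad, (arg.ravel(), cols.ravel()), g.ravel())

    return _from_op(out_data, (x,), backward)


# Classification head -----------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64).ravel()
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def softmax_cross_entropy(logits: Tensor, label: int) -> Tensor:
    """-log softmax(logits)[label]; ``logits`` is (1, n) or (n,)."""
    p = softmax(logits.data)
    loss = -np.log(max(p[label], 1e-300))

    def backward(g):
        d = p.copy()
        d[label] -= 1.0
        _accum(logits, (g * d).reshape(logits.data.shape))

    return _from_op(loss, (logits,), backward)
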