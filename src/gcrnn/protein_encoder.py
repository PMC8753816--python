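"""Protein sequence encoder: overlapping 3-gram words, convolution stack,
windowed max-pooling.

An amino-acid sequence of length L becomes L - n + 1 overlapping n-gram
words (stride 1, n = 3 by default); each word id indexes a learned embedding
row.  The embedded sequence runs through a stack of 1-D convolutions
(ReLU, no bias, "same" zero padding) and one windowed max-pooling layer.
Pooling keeps the final partial window, so any non-empty input yields at
least one output row; the channel count — not the position count — is what
the downstream readout depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Architecture of the reference model: three conv layers of 320 kernels with
# window 30, then max-pooling with window 15 and stride 15.
DEFAULT_CONV_LAYERS = 3
DEFAULT_KERNELS = 320
DEFAULT_WINDOW = 30
DEFAULT_POOL_WINDOW = 15
DEFAULT_POOL_STRIDE = 15
DEFAULT_EMBED_DIM = 32
DEFAULT_NGRAM = 3
INIT_SCALE = 0.1


@dataclass
class ProteinTokenSequence:
    """Overlapping n-gram word ids of one protein."""

    word_ids: list[int]
    n: int


def word_vocab_size(n: int) -> int:
    """20^n in-alphabet words plus one reserved UNK row (the last)."""
    return 20 ** n + 1


def unk_word_id(n: int) -> int:
    return 20 ** n


def encode_ngrams(sequence: str, n: int = DEFAULT_NGRAM) -> ProteinTokenSequence:
    """Stride-1 overlapping n-gram ids; base-20 positional code per word.

    Any word containing a character outside the 20 standard one-letter codes
    maps to the reserved UNK id.
    """
    if n < 1:
        raise ValueError("gram size must be positive")
    if len(sequence) < n:
        raise ValueError(
            f"sequence of length {len(sequence)} shorter than gram size {n}")
    unk = unk_word_id(n)
    ids = []
    for i in range(len(sequence) - n + 1):
        word = sequence[i:i + n]
        code = 0
        for ch in word:
            k = _AA_INDEX.get(ch)
            if k is None:
                code = unk
                break
            code = code * 20 + k
        ids.append(code)
    return ProteinTokenSequence(word_ids=ids, n=n)


@dataclass
class CNNParams:
    """Word embedding table plus the convolution stack and pooling geometry.

    ``conv_weights[t]`` has shape (K, M, C): K kernels, window M, C input
    channels (C equals the embedding width for the first layer and K for
    the deeper ones).
    """

    word_embed: Tensor
    conv_weights: list[Tensor]
    pool_window: int
    pool_stride: int
    ngram: int

    @property
    def out_channels(self) -> int:
        return self.conv_weights[-1].shape[0]

    def named_tensors(self):
        yield "cnn.word_embed", self.word_embed
        for t, w in enumerate(self.conv_weights):
            yield f"cnn.conv{t}.W", w


def init_cnn(n_layers: int = DEFAULT_CONV_LAYERS,
             kernels: int = DEFAULT_KERNELS,
             window: int = DEFAULT_WINDOW,
             pool_window: int = DEFAULT_POOL_WINDOW,
             pool_stride: int = DEFAULT_POOL_STRIDE,
             embed_dim: int = DEFAULT_EMBED_DIM,
             ngram: int = DEFAULT_NGRAM,
             seed: int = 0) -> CNNParams:
    rng = np.random.default_rng(seed)

    def u(*shape):
        return ad.parameter(rng.uniform(-INIT_SCALE, INIT_SCALE, shape))

    weights = []
    c = embed_dim
    for _ in range(n_layers):
        weights.append(u(kernels, window, c))
        c = kernels
    return CNNParams(word_embed=u(word_vocab_size(ngram), embed_dim),
                     conv_weights=weights,
                     pool_window=pool_window, pool_stride=pool_stride,
                     ngram=ngram)


def conv_forward(x: Tensor, w: Tensor) -> Tensor:
    """out[i, k] = ReLU(sum_{m,c} W[k, m, c] x[i+m, c]), "same" padding."""
    return ad.relu(ad.conv1d_same(x, w))


def max_pool(x: Tensor, window: int, stride: int) -> Tensor:
    """Per-channel max over fixed windows; final partial window kept."""
    return ad.maxpool1d(x, window, stride)


def encode_protein(tokens: ProteinTokenSequence, params: CNNParams) -> Tensor:
    """Embed word ids, run the conv stack, pool; returns (positions, K)."""
    x = ad.take(params.word_embed, np.asarray(tokens.word_ids, dtype=np.intp))
    for w in params.conv_weights:
        x = conv_forward(x, w)
    return max_pool(x, params.pool_window, params.pool_stride)
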