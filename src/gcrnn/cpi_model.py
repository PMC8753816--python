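"""End-to-end compound-protein interaction model.

The compound branch (GNN over r-radius fingerprints) yields y_molecule of
width d; the protein branch (3-gram embedding -> conv stack -> windowed
max-pooling -> bidirectional recurrent stack -> mean readout) yields
y_protein.  The head is

    p = softmax(W_out [y_molecule ; y_protein] + b_out)

over the two classes (no interaction / interaction), trained with
cross-entropy -ln p_label and thresholded at p_1 >= 0.5.

``cell="none"`` is the no-recurrent ablation: the protein branch stops at
the pooled convolution features, whose per-position mean becomes y_protein.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from . import compound_gnn, protein_encoder, recurrent_encoder
from .autodiff import Tensor
from .compound_gnn import GNNParams, GraphIndex
from .mol_graph import (FingerprintedGraph, SubgraphVocabulary,
                        assign_fingerprints, parse_smiles)
from .protein_encoder import CNNParams, ProteinTokenSequence, encode_ngrams
from .recurrent_encoder import BiRNNParams

CELL_TYPES = ("lstm", "gru", "none")


@dataclass
class ModelConfig:
    """All architecture settings.  Defaults are the reference geometry:
    radius-2 fingerprints with a 3-layer GNN; 3 conv layers of 320 kernels,
    window 30; pooling 15/15; two bidirectional layers of 320 units."""

    cell: str = "lstm"
    radius: int = 2
    mol_dim: int = 10
    gnn_layers: int = 3
    ngram: int = 3
    embed_dim: int = 32
    conv_layers: int = 3
    kernels: int = 320
    conv_window: int = 30
    pool_window: int = 15
    pool_stride: int = 15
    rnn_hidden: int = 320
    rnn_layers: int = 2
    rnn_out: int | None = None   # defaults to rnn_hidden
    max_seq_len: int = 1000      # proteins longer than this are tail-truncated

    def __post_init__(self):
        if self.cell not in CELL_TYPES:
            raise ValueError(f"cell must be one of {CELL_TYPES}, got {self.cell!r}")
        if self.rnn_out is None:
            self.rnn_out = self.rnn_hidden

    @property
    def protein_dim(self) -> int:
        return self.kernels if self.cell == "none" else self.rnn_out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class ModelParams:
    """All learnable arrays plus the frozen fingerprint vocabulary."""

    gnn: GNNParams
    cnn: CNNParams
    rnn: BiRNNParams | None
    W_out: Tensor            # (mol_dim + protein_dim, 2)
    b_out: Tensor            # (2,)
    config: ModelConfig
    vocab: SubgraphVocabulary
    seed: int = 0

    def named_tensors(self):
        yield from self.gnn.named_tensors()
        yield from self.cnn.named_tensors()
        if self.rnn is not None:
            yield from self.rnn.named_tensors()
        yield "head.W_out", self.W_out
        yield "head.b_out", self.b_out

    def tensors(self) -> list[Tensor]:
        return [t for _, t in self.named_tensors()]

    def zero_grad(self) -> None:
        for t in self.tensors():
            t.zero_grad()


def init_model(config: ModelConfig, vocab: SubgraphVocabulary,
               seed: int = 0) -> ModelParams:
    """Initialize every parameter group from one seed (uniform [-0.1, 0.1])."""
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    gnn = compound_gnn.init_gnn(vocab.node_vocab_size, vocab.edge_vocab_size,
                                d=config.mol_dim, T=config.gnn_layers,
                                seed=sub[0])
    cnn = protein_encoder.init_cnn(n_layers=config.conv_layers,
                                   kernels=config.kernels,
                                   window=config.conv_window,
                                   pool_window=config.pool_window,
                                   pool_stride=config.pool_stride,
                                   embed_dim=config.embed_dim,
                                   ngram=config.ngram, seed=sub[1])
    rnn = None
    if config.cell != "none":
        rnn = recurrent_encoder.init_birnn(input_dim=config.kernels,
                                           hidden=config.rnn_hidden,
                                           out_dim=config.rnn_out,
                                           n_layers=config.rnn_layers,
                                           cell=config.cell, seed=sub[2])
    head_rng = np.random.default_rng(sub[3])
    head_in = config.mol_dim + config.protein_dim
    W_out = ad.parameter(head_rng.uniform(-0.1, 0.1, (head_in, 2)))
    b_out = ad.parameter(head_rng.uniform(-0.1, 0.1, 2))
    return ModelParams(gnn=gnn, cnn=cnn, rnn=rnn, W_out=W_out, b_out=b_out,
                       config=config, vocab=vocab, seed=seed)


@dataclass
class PreparedExample:
    """Parsed and fingerprinted inputs, cacheable across epochs."""

    fpg: FingerprintedGraph
    index: GraphIndex
    tokens: ProteinTokenSequence
    label: int | None = None


def prepare_example(smiles: str, sequence: str, params: ModelParams,
                    label: int | None = None,
                    allow_grow: bool = False) -> PreparedExample:
    graph = parse_smiles(smiles)
    fpg = assign_fingerprints(graph, params.config.radius, params.vocab,
                              allow_grow=allow_grow)
    seq = sequence[:params.config.max_seq_len]
    tokens = encode_ngrams(seq, params.config.ngram)
    return PreparedExample(fpg=fpg, index=GraphIndex(graph), tokens=tokens,
                           label=label)


def forward_prepared(ex: PreparedExample, params: ModelParams) -> tuple[np.ndarray, Tensor]:
    """Class probabilities (p_0, p_1) and the logits tensor (for backprop)."""
    y_mol = compound_gnn.embed_molecule(ex.fpg, params.gnn, ex.index)
    feats = protein_encoder.encode_protein(ex.tokens, params.cnn)
    if params.rnn is not None:
        feats = recurrent_encoder.bidirectional_encode(feats, params.rnn)
    y_prot = recurrent_encoder.protein_readout(feats)
    joint = ad.concat([y_mol, y_prot], axis=1)
    logits = ad.add(ad.matmul(joint, params.W_out), params.b_out)
    return ad.softmax(logits.data), logits


def forward(smiles: str, sequence: str, params: ModelParams) -> np.ndarray:
    """Probability pair for one (SMILES, sequence); vocabulary stays frozen."""
    ex = prepare_example(smiles, sequence, params, allow_grow=False)
    probs, _ = forward_prepared(ex, params)
    return probs


def loss(p, label: int) -> float:
    """Cross-entropy -ln p_label of a probability pair."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    p = np.asarray(p, dtype=np.float64).ravel()
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    return float(-np.log(max(p[label], 1e-300)))


def training_loss(ex: PreparedExample, params: ModelParams) -> tuple[Tensor, np.ndarray]:
    """Differentiable cross-entropy for one example; also returns probs."""
    probs, logits = forward_prepared(ex, params)
    return ad.softmax_cross_entropy(logits, ex.label), probs


def predict_label(p) -> int:
    """Decision rule: interaction iff p_1 >= 0.5."""
    p = np.asarray(p).ravel()
    return int(p[1] >= 0.5)
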