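"""Dataset splitting, the training recipe, and confusion-matrix evaluation.

Training follows the reference recipe: Adam, learning rate 0.001 decayed by
a factor of 0.4 every 10 epochs (interval configurable), 100 epochs by
default, per-example updates (graphs and sequences are variable-sized), and
model selection by best validation accuracy.  Data are split 65/20/15 into
train/validation/test, stratified by label by default.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import cpi_model
from .autodiff import Tensor
from .cpi_model import ModelConfig, ModelParams, PreparedExample
from .mol_graph import SubgraphVocabulary, assign_fingerprints, parse_smiles

logger = logging.getLogger("gcrnn")

SPLITS = ("train", "valid", "test")
DEFAULT_FRACTIONS = (0.65, 0.20, 0.15)


@dataclass
class CPIDataset:
    """(SMILES, sequence, label) triples plus an optional split assignment."""

    examples: list[tuple[str, str, int]]
    split: list[str] | None = None

    def __post_init__(self):
        for i, (_, _, label) in enumerate(self.examples):
            if label not in (0, 1):
                raise ValueError(f"example {i}: label must be 0 or 1, got {label!r}")
        if self.split is not None and len(self.split) != len(self.examples):
            raise ValueError("split length does not match example count")

    def __len__(self) -> int:
        return len(self.examples)

    def subset(self, tag: str) -> list[tuple[str, str, int]]:
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        return [ex for ex, s in zip(self.examples, self.split) if s == tag]


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the reference recipe."""

    epochs: int = 100
    learning_rate: float = 1e-3
    lr_decay: float = 0.4
    decay_interval: int = 10
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")

    def lr_at(self, epoch: int) -> float:
        """Stepped schedule: lr * decay^(epoch // interval), epochs 0-based."""
        return self.learning_rate * self.lr_decay ** (epoch // self.decay_interval)


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "MetricsReport":
        def ratio(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator); reporting 0")
                return 0.0
            return num / den

        precision = ratio(tp, tp + fp, "precision")
        recall = ratio(tp, tp + fn, "recall")
        accuracy = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
        f1 = ratio(2 * precision * recall, precision + recall, "F1") \
            if (precision + recall) > 0 else 0.0
        return cls(tp=tp, tn=tn, fp=fp, fn=fn, precision=precision,
                   recall=recall, accuracy=accuracy, f1=f1)


def split_dataset(data: CPIDataset, fractions=DEFAULT_FRACTIONS,
                  seed: int = 0, stratify: bool = True) -> CPIDataset:
    """Assign train/valid/test tags (65/20/15 by default).

    Split sizes are round(f * n) for valid and test with the remainder going
    to train.  With ``stratify`` (the default; CPI corpora are balanced) the
    shuffled order interleaves classes so every split preserves the label
    ratio to within one example.
    """
    n = len(data)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    labels = np.array([ex[2] for ex in data.examples])
    if stratify:
        # Sort by within-class quantile with random tie-breaks: cutting the
        # order anywhere keeps each class's share within one example.
        key = np.empty(n)
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            perm = rng.permutation(len(idx))
            key[idx] = (perm + rng.random(len(idx))) / len(idx)
        order = np.argsort(key)
    else:
        order = rng.permutation(n)
    n_valid = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_valid - n_test
    split = [""] * n
    for pos, i in enumerate(order):
        if pos < n_train:
            split[i] = "train"
        elif pos < n_train + n_valid:
            split[i] = "valid"
        else:
            split[i] = "test"
    return CPIDataset(examples=list(data.examples), split=split)


def build_vocabulary(examples, radius: int) -> SubgraphVocabulary:
    """Fingerprint vocabulary grown over the training compounds, then frozen."""
    vocab = SubgraphVocabulary(radius=radius)
    for smiles, _, _ in examples:
        assign_fingerprints(parse_smiles(smiles), radius, vocab, allow_grow=True)
    vocab.freeze()
    return vocab


class AdamOptimizer:
    """Adam with bias correction; one slot pair per parameter tensor."""

    def __init__(self, tensors: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.tensors = tensors
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, tensor in enumerate(self.tensors):
            g = tensor.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            tensor.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _prepare_all(examples, params: ModelParams, allow_grow: bool) -> list[PreparedExample]:
    return [cpi_model.prepare_example(s, q, params, label=y, allow_grow=allow_grow)
            for s, q, y in examples]


def _eval_prepared(prepared: list[PreparedExample], params: ModelParams):
    losses, correct = [], 0
    for ex in prepared:
        probs, _ = cpi_model.forward_prepared(ex, params)
        losses.append(cpi_model.loss(probs, ex.label))
        correct += int(cpi_model.predict_label(probs) == ex.label)
    n = max(len(prepared), 1)
    return float(np.mean(losses)) if losses else float("nan"), correct / n


def train(data: CPIDataset, config: TrainConfig) -> tuple[ModelParams, list[dict]]:
    """Train on the train split, monitor the valid split, return the
    best-validation-accuracy parameters and the per-epoch log."""
    if data.split is None:
        data = split_dataset(data, seed=config.seed)
    train_ex = data.subset("train")
    valid_ex = data.subset("valid")
    if not train_ex:
        raise ValueError("training split is empty")

    vocab = build_vocabulary(train_ex, config.model.radius)
    params = cpi_model.init_model(config.model, vocab, seed=config.seed)
    prepared_train = _prepare_all(train_ex, params, allow_grow=False)
    prepared_valid = _prepare_all(valid_ex, params, allow_grow=False)

    optimizer = AdamOptimizer(params.tensors(), beta1=config.adam_beta1,
                              beta2=config.adam_beta2, eps=config.adam_eps)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    best_acc, best_params = -1.0, None

    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(prepared_train))
        epoch_losses, correct = [], 0
        for i in order:
            ex = prepared_train[i]
            params.zero_grad()
            loss_t, probs = cpi_model.training_loss(ex, params)
            loss_val = float(loss_t.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at epoch {epoch}, example {i}")
            loss_t.backward()
            optimizer.step(lr)
            epoch_losses.append(loss_val)
            correct += int(cpi_model.predict_label(probs) == ex.label)
        val_loss, val_acc = _eval_prepared(prepared_valid, params)
        entry = {"epoch": epoch, "lr": lr,
                 "train_loss": float(np.mean(epoch_losses)),
                 "train_acc": correct / len(prepared_train),
                 "val_loss": val_loss, "val_acc": val_acc}
        log.append(entry)
        logger.info("epoch %(epoch)d lr=%(lr).2e train_loss=%(train_loss).4f "
                    "train_acc=%(train_acc).3f val_loss=%(val_loss).4f "
                    "val_acc=%(val_acc).3f", entry)
        if prepared_valid and val_acc > best_acc:
            best_acc = val_acc
            best_params = _copy_params(params)
    if best_params is None:
        best_params = _copy_params(params)
    return best_params, log


def _copy_params(params: ModelParams) -> ModelParams:
    clone = copy.deepcopy(params)
    for t in clone.tensors():
        t.zero_grad()
    return clone


def predict_dataset(params: ModelParams, examples) -> list[int]:
    preds = []
    for smiles, sequence, _ in examples:
        preds.append(cpi_model.predict_label(
            cpi_model.forward(smiles, sequence, params)))
    return preds


def evaluate(params: ModelParams, data: CPIDataset, split: str = "test") -> MetricsReport:
    """Confusion counts and derived metrics on one split."""
    examples = data.subset(split) if data.split is not None else data.examples
    if not examples:
        raise ValueError(f"split {split!r} is empty")
    preds = predict_dataset(params, examples)
    tp = tn = fp = fn = 0
    for (_, _, label), pred in zip(examples, preds):
        if pred == 1 and label == 1:
            tp += 1
        elif pred == 0 and label == 0:
            tn += 1
        elif pred == 1 and label == 0:
            fp += 1
        else:
            fn += 1
    return MetricsReport.from_counts(tp, tn, fp, fn)
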