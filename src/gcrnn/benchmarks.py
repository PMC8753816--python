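"""Desk-scale benchmark runs on the planted-rule synthetic data.

The full reference geometry (320 kernels, 320 recurrent units, 7000 pairs,
100 epochs) is a GPU-scale workload; these benchmarks exercise the identical
pipeline at desk scale: n = 300 pairs, a small model (d = 10, K = 8 kernels
of window 5, hidden width 8) and 15-30 epochs, which suffices for the
planted AND rule to be learned essentially perfectly.

Two studies are provided:

* ``learning_benchmark`` - train on the noise-free AND-rule data and report
  test accuracy; with ``shuffle_labels`` the labels are permuted first, so
  any accuracy far from chance would indicate leakage.
* ``ablation_benchmark`` - mean test accuracy over seeds of the recurrent
  model vs the no-recurrent (CNN-only protein branch) ablation on noisy
  labels.
"""

from __future__ import annotations

import numpy as np

from .cpi_model import ModelConfig
from .synthetic_data import SynthConfig, generate_dataset
from .train_eval import CPIDataset, TrainConfig, evaluate, split_dataset, train


def small_model(cell: str = "gru") -> ModelConfig:
    """The desk-scale geometry used throughout the benchmarks and tests."""
    return ModelConfig(cell=cell, mol_dim=10, embed_dim=32, conv_layers=3,
                       kernels=8, conv_window=5, pool_window=15,
                       pool_stride=15, rnn_hidden=8, rnn_layers=2, rnn_out=8)


def shuffle_labels(data: CPIDataset, seed: int) -> CPIDataset:
    """Permute labels across examples (features untouched)."""
    rng = np.random.default_rng(seed)
    labels = [ex[2] for ex in data.examples]
    perm = rng.permutation(len(labels))
    return CPIDataset(examples=[(s, q, int(labels[p]))
                                for (s, q, _), p in zip(data.examples, perm)])


def learning_benchmark(seed: int = 0, n: int = 300, noise: float = 0.0,
                       cell: str = "gru", epochs: int = 30,
                       shuffled: bool = False) -> dict:
    """Train the small model on the AND-rule data; report the test metrics."""
    data = generate_dataset(SynthConfig(n_examples=n, seed=seed,
                                        label_noise=noise))
    if shuffled:
        data = shuffle_labels(data, seed=seed + 1)
    data = split_dataset(data, seed=seed)
    config = TrainConfig(epochs=epochs, seed=seed, model=small_model(cell))
    params, log = train(data, config)
    report = evaluate(params, data, "test")
    return {"report": report, "log": log, "params": params, "data": data,
            "test_accuracy": report.accuracy,
            "n_test": report.tp + report.tn + report.fp + report.fn}


def ablation_benchmark(seeds=(0, 1, 2, 3, 4), n: int = 300,
                       noise: float = 0.1, epochs: int = 15,
                       cells=("gru", "none")) -> dict:
    """Mean test accuracy per cell type over seeds, same data per seed."""
    accs = {cell: [] for cell in cells}
    for seed in seeds:
        data = generate_dataset(SynthConfig(n_examples=n, seed=seed,
                                            label_noise=noise))
        data = split_dataset(data, seed=seed)
        for cell in cells:
            config = TrainConfig(epochs=epochs, seed=seed,
                                 model=small_model(cell))
            params, _ = train(data, config)
            accs[cell].append(evaluate(params, data, "test").accuracy)
    return {cell: {"accuracies": a, "mean": float(np.mean(a))}
            for cell, a in accs.items()}
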