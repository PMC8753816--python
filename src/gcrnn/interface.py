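"""Dataset and model I/O.

The dataset format is a headerless UTF-8 TSV with three columns — compound
SMILES, protein sequence, binary label — one pair per line, LF endings.
Checkpoints are NumPy ``.npz`` archives holding every parameter array under
its qualified name plus the fingerprint vocabulary, the model configuration
and the training seed as JSON; a version field guards the layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import cpi_model
from .cpi_model import ModelConfig, ModelParams
from .mol_graph import SubgraphVocabulary
from .train_eval import CPIDataset

CHECKPOINT_VERSION = 1


class DatasetFormatError(ValueError):
    pass


def read_dataset(path: str | Path) -> CPIDataset:
    """Read a 3-column TSV; fails fast listing every malformed row."""
    path = Path(path)
    examples = []
    errors = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                errors.append(f"line {lineno}: expected 3 fields, got {len(fields)}")
                continue
            smiles, sequence, label_str = fields
            if label_str not in ("0", "1"):
                errors.append(f"line {lineno}: label must be 0 or 1, got {label_str!r}")
                continue
            examples.append((smiles, sequence, int(label_str)))
    if errors:
        raise DatasetFormatError(
            f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return CPIDataset(examples=examples)


def write_dataset(data: CPIDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for smiles, sequence, label in data.examples:
            fh.write(f"{smiles}\t{sequence}\t{label}\n")


def write_fasta(data: CPIDataset, path: str | Path) -> None:
    """Companion FASTA of the protein sequences (one record per pair)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for i, (_, sequence, _) in enumerate(data.examples):
            fh.write(f">pair_{i}\n{sequence}\n")


def fasta_to_pairs(fasta_path: str | Path, smiles: list[str],
                   labels: list[int]) -> CPIDataset:
    """Zip a FASTA of proteins with SMILES and labels into a dataset."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not (len(records) == len(smiles) == len(labels)):
        raise ValueError("FASTA record, SMILES and label counts differ")
    examples = [(s, str(r.seq), int(y))
                for s, r, y in zip(smiles, records, labels)]
    return CPIDataset(examples=examples)


def save_checkpoint(params: ModelParams, path: str | Path) -> None:
    arrays = {f"param/{name}": t.data for name, t in params.named_tensors()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": params.config.to_dict(),
        "vocab": json.loads(params.vocab.to_json()),
        "seed": params.seed,
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ModelParams:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')!r} unsupported "
                f"(expected {CHECKPOINT_VERSION})")
        config = ModelConfig.from_dict(meta["config"])
        vocab = SubgraphVocabulary.from_json(json.dumps(meta["vocab"]))
        params = cpi_model.init_model(config, vocab, seed=int(meta["seed"]))
        for name, tensor in params.named_tensors():
            key = f"param/{name}"
            if key not in archive:
                raise ValueError(f"corrupt checkpoint: missing array {name}")
            stored = archive[key]
            if stored.shape != tensor.data.shape:
                raise ValueError(f"corrupt checkpoint: shape mismatch for {name}")
            tensor.data = stored.astype(np.float64)
    return params


def write_training_log(log: list[dict], path: str | Path) -> None:
    """Per-epoch CSV: epoch, lr, train_loss, train_acc, val_loss, val_acc."""
    cols = ("epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc")
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(cols) + "\n")
        for row in log:
            fh.write(",".join(repr(row[c]) for c in cols) + "\n")
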