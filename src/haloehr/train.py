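"""Dataset splitting and the optimization loop.

Defaults mirror the reference experimental setup: Adam at learning rate 1e-4,
batch size 48, 50 epochs, an 0.8/0.2 train-test split with a further 0.9/0.1
train-validation split, and checkpoint selection by lowest validation loss
(the same masked BCE as the training objective).  Gradients are clipped at
global norm 1.0 to keep tiny-batch runs stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import HALOModel, ModelConfig, masked_bce_loss
from .records import encode_record


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 48
    epochs: int = 50
    test_fraction: float = 0.2
    val_fraction: float = 0.1
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1 or not 0 < self.val_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def make_splits(records, test_fraction: float = 0.2, val_fraction: float = 0.1,
                seed: int = 0):
    """Disjoint, exhaustive (train, validation, test) split; train size is
    floor((1-test)*(1-val) * n) via two successive floors, e.g. 100 -> 72/8/20."""
    records = list(records)
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    idx = np.random.default_rng(seed).permutation(n)
    n_trainval = math.floor((1.0 - test_fraction) * n)
    n_train = math.floor((1.0 - val_fraction) * n_trainval)
    train = [records[i] for i in idx[:n_train]]
    val = [records[i] for i in idx[n_train:n_trainval]]
    test = [records[i] for i in idx[n_trainval:]]
    return train, val, test


@dataclass
class EncodedDataset:
    """Dense encoded cohort: matrices (n, T_max+3, C) and row counts (n,)."""

    matrices: np.ndarray
    lengths: np.ndarray

    @classmethod
    def from_records(cls, records, vocab, schemes=(), t_max: int = 10):
        records = list(records)
        mats = np.zeros((len(records), t_max + 3, len(vocab)), dtype=np.float64)
        lengths = np.zeros(len(records), dtype=int)
        for i, r in enumerate(records):
            rm = encode_record(r, vocab, schemes, t_max)
            mats[i] = rm.matrix
            lengths[i] = rm.n_rows
        return cls(mats, lengths)

    def __len__(self):
        return len(self.lengths)

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        """Yield (matrix, lengths) batches, each trimmed to its own max row
        count; loss masking makes the trim/pad choice loss-neutral."""
        order = np.arange(len(self)) if rng is None else rng.permutation(len(self))
        for start in range(0, len(self), batch_size):
            sel = order[start:start + batch_size]
            ln = self.lengths[sel]
            L = int(ln.max())
            yield self.matrices[sel][:, :L, :], ln


def evaluate_loss(model: HALOModel, data: EncodedDataset, batch_size: int = 64) -> float:
    """Masked BCE averaged over all scored cells of a dataset."""
    total, cells = 0.0, 0
    for X, ln in data.batches(batch_size):
        O = model.code_probabilities(X)
        n = float(np.sum(np.maximum(ln - 1, 0)) * model.config.C)
        total += masked_bce_loss(O, X, ln) * n
        cells += n
    return total / cells


def train_model(
    train_data: EncodedDataset,
    val_data: EncodedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    log_path=None,
    verbose: bool = False,
):
    """Run Adam on the masked BCE objective and return the model restored to
    the epoch with lowest validation loss, plus the per-epoch history."""
    model = HALOModel(model_config)
    opt = nn.Adam(model.params, lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    drop_rng = np.random.default_rng(rng.integers(2**31)) \
        if model_config.dropout > 0 else None

    history = []
    best = {"val_loss": np.inf, "params": model.copy_params(), "epoch": -1}
    log_fh = open(log_path, "w", encoding="utf-8") if log_path else None
    try:
        for epoch in range(train_config.epochs):
            running, nb = 0.0, 0
            for X, ln in train_data.batches(train_config.batch_size, rng):
                loss, grads = model.loss_and_grads(X, ln, train_rng=drop_rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                grads = nn.clip_by_global_norm(grads, train_config.clip_norm)
                opt.step(model.params, grads)
                running += loss
                nb += 1
            val_loss = evaluate_loss(model, val_data)
            if not np.isfinite(val_loss):
                raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
            entry = {"epoch": epoch, "train_loss": running / max(nb, 1),
                     "val_loss": val_loss}
            history.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
            if verbose:
                print(f"epoch {epoch}: train {entry['train_loss']:.5f} "
                      f"val {val_loss:.5f}")
            if val_loss < best["val_loss"]:
                best = {"val_loss": val_loss, "params": model.copy_params(),
                        "epoch": epoch}
    finally:
        if log_fh:
            log_fh.close()
    model.params = best["params"]
    model.best_epoch = best["epoch"]
    return model, history


def marginal_baseline_log_probability(train_data: EncodedDataset,
                                      test_data: EncodedDataset) -> np.ndarray:
    """Per-record log-likelihoods under an independence baseline: each code is
    Bernoulli with its marginal frequency over scored rows of the training set
    (the floor of structure-free modeling, used to sanity-check training)."""
    from .model import PROB_FLOOR, scored_row_mask

    mask = scored_row_mask(train_data.lengths, train_data.matrices.shape[1] - 1)
    tgt = train_data.matrices[:, 1:, :]
    n_rows = mask.sum()
    p = (tgt * mask[:, :, None]).sum(axis=(0, 1)) / n_rows
    p = np.clip(p, PROB_FLOOR, 1 - PROB_FLOOR)

    mask_t = scored_row_mask(test_data.lengths, test_data.matrices.shape[1] - 1)
    tgt_t = test_data.matrices[:, 1:, :]
    cell = tgt_t * np.log(p) + (1 - tgt_t) * np.log1p(-p)
    return (cell * mask_t[:, :, None]).sum(axis=(1, 2))
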