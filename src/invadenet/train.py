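"""End-to-end training: AdamW on mean binary cross-entropy with seeded
shuffling, optional minority oversampling with intensity jitter, early
stopping on validation loss and per-epoch logging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evalstats import roc_auc
from .head import bce_loss, bce_loss_grad
from .model import InvasionNet
from .nn import AdamW, set_training

__all__ = ["TrainConfig", "TrainResult", "TrainingDivergedError", "train_model"]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    weight_decay: float = 1e-4
    oversample_minority: bool = True
    #: SD of the Gaussian intensity jitter added to oversampled duplicates
    oversample_jitter: float = 0.02
    #: SD of Gaussian jitter applied to every training batch (regularizer)
    input_jitter: float = 0.0
    #: random 90-degree rotations / flips per training sample (exact,
    #: interpolation-free; valid whenever axial orientation is arbitrary)
    dihedral_augment: bool = False
    seed: int = 0


@dataclass
class TrainResult:
    history: pd.DataFrame  # epoch, train_loss, val_loss, val_auc
    best_epoch: int
    best_val_loss: float
    best_state: dict = field(repr=False, default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.history)


def _epoch_indices(
    y: np.ndarray, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled sample indices for one epoch; oversampled minority
    duplicates are flagged so they can receive intensity jitter."""
    idx = np.arange(len(y))
    extra_flag = np.zeros(len(y), dtype=bool)
    if cfg.oversample_minority:
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) == 2 and counts.min() < counts.max():
            minority = classes[np.argmin(counts)]
            extra = rng.choice(
                np.flatnonzero(y == minority), counts.max() - counts.min(), replace=True
            )
            idx = np.concatenate([idx, extra])
            extra_flag = np.concatenate([extra_flag, np.ones(len(extra), dtype=bool)])
    order = rng.permutation(len(idx))
    return idx[order], extra_flag[order]


def train_model(
    model: InvasionNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Optimize the whole network (tokenizer + attention + head jointly);
    returns the history and restores the best-validation-loss weights."""
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(list(model.params()), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rows = []
    best_val = np.inf
    best_epoch = -1
    best_state: dict = {}
    since_best = 0
    for epoch in range(cfg.max_epochs):
        set_training(model, True)
        idx, extras = _epoch_indices(y_train, cfg, rng)
        n_seen = 0
        loss_sum = 0.0
        for start in range(0, len(idx), cfg.batch_size):
            take = idx[start : start + cfg.batch_size]
            xb = x_train[take]
            dup = extras[start : start + cfg.batch_size]
            if cfg.oversample_jitter > 0 and dup.any():
                xb = xb.copy()
                xb[dup] += rng.normal(
                    0, cfg.oversample_jitter, xb[dup].shape
                ).astype(xb.dtype)
            if cfg.dihedral_augment:
                xb = xb.copy()
                for i in range(len(xb)):
                    k = int(rng.integers(4))
                    if k:
                        xb[i] = np.rot90(xb[i], k, axes=(2, 3))
                    if rng.random() < 0.5:
                        xb[i] = xb[i, :, :, :, ::-1]
            if cfg.input_jitter > 0:
                xb = xb + rng.normal(0, cfg.input_jitter, xb.shape).astype(xb.dtype)
            yb = y_train[take]
            yp = model.forward(xb)
            loss = bce_loss(yp, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}"
                )
            opt.zero_grad()
            model.backward(bce_loss_grad(yp, yb))
            opt.step()
            loss_sum += loss * len(take)
            n_seen += len(take)
        val_scores = model.predict_proba(x_val)
        val_loss = bce_loss(val_scores, y_val)
        try:
            val_auc = roc_auc(val_scores, y_val)[0]
        except ValueError:  # single-class validation split
            val_auc = np.nan
        rows.append(
            {"epoch": epoch, "train_loss": loss_sum / n_seen,
             "val_loss": val_loss, "val_auc": val_auc}
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state:
        model.load_state_dict(best_state)
    return TrainResult(
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        best_state=best_state,
    )
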