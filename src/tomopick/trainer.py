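"""Training harness: AdamW loop with plateau LR halving and early stopping.

The schedule follows common practice for this task: at most 150 epochs,
batches of ten cubes, initial learning rate 4e-4 halved after six epochs
without validation improvement, decoupled weight decay 1e-10, and early
stopping with a patience of 36 epochs; 20% of the cube pairs are held out
for validation.  The checkpoint returned is the one with the best validation
loss, not the last.  Fine-tuning resumes from a saved checkpoint with the
same loop semantics (conventionally ~20 epochs at a 5e-5 learning rate).

"Improvement" means the validation loss drops below the running best by more
than 1e-6 absolute; both the scheduler and early stopping share that
definition, evaluated once per epoch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import BackboneContract, load_backbone
from .loss import LossConfig, composite_loss_grad, composite_loss

__all__ = ["TrainConfig", "TrainResult", "split_train_val", "train", "fine_tune"]

_IMPROVEMENT_TOL = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 150
    early_stop_patience: int = 36
    batch_size: int = 10
    lr: float = 4e-4
    lr_factor: float = 0.5
    lr_patience: int = 6
    weight_decay: float = 1e-10
    val_fraction: float = 0.2
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.early_stop_patience < 1 or self.lr_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not self.lr > 0:
            raise ValueError(f"lr must be > 0, got {self.lr}")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainResult:
    """Outcome of a training run: backbone carries the best-epoch weights."""

    backbone: BackboneContract
    log: list[dict]
    best_epoch: int
    best_val_loss: float

    def write_log(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss", "lr"])
            writer.writeheader()
            writer.writerows(self.log)


def split_train_val(
    chunks: list, val_fraction: float = 0.2, seed: int = 0
) -> tuple[list, list]:
    """Disjoint, exhaustive random split; val gets ``round(val_fraction * n)``."""
    n = len(chunks)
    if n < 2:
        raise ValueError(f"need at least 2 chunks to split, got {n}")
    n_val = int(round(val_fraction * n))
    n_val = min(max(n_val, 1), n - 1)  # both sides non-empty
    perm = np.random.default_rng(seed).permutation(n)
    val_idx = set(perm[:n_val].tolist())
    train_set = [chunks[i] for i in range(n) if i not in val_idx]
    val_set = [chunks[i] for i in range(n) if i in val_idx]
    return train_set, val_set


class _AdamW:
    """Decoupled-weight-decay Adam on a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for key, p in self.params.items():
            g = grads[key].astype(np.float64)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / bias1
            v_hat = self.v[key] / bias2
            p -= (self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p)).astype(
                p.dtype
            )


def _epoch_val_loss(backbone: BackboneContract, val_set, loss_cfg: LossConfig) -> float:
    losses = [
        composite_loss(backbone.forward(img), lbl, loss_cfg) for img, lbl in val_set
    ]
    return float(np.mean(losses))


def train(
    backbone: BackboneContract,
    data: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig = TrainConfig(),
    checkpoint_path: str | Path | None = None,
    checkpoint_meta: dict | None = None,
    _presplit: tuple[list, list] | None = None,
) -> TrainResult:
    """Optimize the composite loss over (image, label) cube pairs.

    Splits ``data`` into train/validation (``config.val_fraction``), runs
    AdamW with per-epoch shuffling, halves the learning rate after
    ``lr_patience`` epochs without validation improvement, stops early after
    ``early_stop_patience`` such epochs, and restores the best-validation
    weights before returning.  Deterministic for a fixed seed.
    """
    if not data:
        raise ValueError("no training data")
    if _presplit is not None:
        train_set, val_set = _presplit
    else:
        train_set, val_set = split_train_val(data, config.val_fraction, config.seed)
    if not val_set:
        raise ValueError("empty validation split")
    rng = np.random.default_rng(config.seed + 1)
    params = backbone.parameters()
    opt = _AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    best_val = np.inf
    best_epoch = 0
    best_params = {k: v.copy() for k, v in params.items()}
    epochs_since_improvement = 0
    epochs_since_lr_event = 0
    log: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_set))
        train_losses: list[float] = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            backbone.zero_grad()
            batch_loss = 0.0
            for img, lbl in batch:
                pred = backbone.forward(img, train=True)
                value, grad = composite_loss_grad(pred, lbl, config.loss)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "check input normalization and learning rate"
                    )
                backbone.backward(grad / len(batch))
                batch_loss += value
            train_losses.append(batch_loss / len(batch))
            if params:
                opt.step(backbone.gradients())
        val_loss = _epoch_val_loss(backbone, val_set, config.loss)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)) if train_losses else np.nan,
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        if val_loss < best_val - _IMPROVEMENT_TOL:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
            epochs_since_improvement = 0
            epochs_since_lr_event = 0
        else:
            epochs_since_improvement += 1
            epochs_since_lr_event += 1
        if epochs_since_improvement >= config.early_stop_patience:
            break
        if epochs_since_lr_event >= config.lr_patience:
            opt.lr *= config.lr_factor
            epochs_since_lr_event = 0
    # restore the best-validation weights
    for key, value in best_params.items():
        params[key][...] = value
    if best_epoch == 0 and log:
        best_val = log[-1]["val_loss"]
        best_epoch = len(log)
    if checkpoint_path is not None:
        meta = {"train_config": _config_to_dict(config), "best_epoch": best_epoch,
                "best_val_loss": None if not np.isfinite(best_val) else best_val}
        meta.update(checkpoint_meta or {})
        backbone.save(checkpoint_path, meta=meta)
    return TrainResult(backbone, log, best_epoch, float(best_val))


def fine_tune(
    checkpoint: str | Path,
    data: list[tuple[np.ndarray, np.ndarray]],
    config_override: dict | None = None,
    checkpoint_path: str | Path | None = None,
) -> TrainResult:
    """Resume training from a saved checkpoint with overridden schedule.

    The conventional recipe is ``{"max_epochs": 20, "lr": 5e-5}``.  With
    ``max_epochs = 0`` the weights are returned unchanged (the log is empty).
    Shape-incompatible checkpoints are rejected with the offending parameter
    names.
    """
    backbone, meta = load_backbone(checkpoint)
    base = meta.get("train_config", {})
    merged = {**{k: v for k, v in base.items() if k in TrainConfig.__dataclass_fields__},
              **(config_override or {})}
    if "loss" in merged and isinstance(merged["loss"], dict):
        merged["loss"] = LossConfig(**merged["loss"])
    config = TrainConfig(**merged)
    if config.max_epochs == 0:
        if checkpoint_path is not None:
            backbone.save(checkpoint_path, meta=meta)
        return TrainResult(backbone, [], best_epoch=0, best_val_loss=np.nan)
    return train(backbone, data, config, checkpoint_path=checkpoint_path,
                 checkpoint_meta={k: v for k, v in meta.items()
                                  if k not in ("train_config", "best_epoch", "best_val_loss")})


def _config_to_dict(config: TrainConfig) -> dict:
    out = {}
    for name in TrainConfig.__dataclass_fields__:
        value = getattr(config, name)
        if isinstance(value, LossConfig):
            value = {"delta": value.delta, "lambda_grad": value.lambda_grad,
                     "grad_order": value.grad_order}
        out[name] = value
    return out
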