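"""Supervised training and block-wise fine-tuning.

Optimization is plain Adam on softmax cross-entropy (soft targets allowed,
so mixup batches train directly). Fine-tuning applies a freeze
configuration and drives the learning rate with a stepwise exponential
scheduler decaying from ``lr_max`` toward a floor of ``lr_min`` with rate
0.8 per epoch. Training is fully deterministic given the config seed on a
fixed platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from . import nn
from .architecture import FreezeConfig, ModelGraph, apply_freeze_config
from .datamodel import CLASSES, ImageRecord
from .preprocess import (AugmentConfig, load_image, mixup_batch,
                         normalize_image, resize_and_crop, standard_augment)

logger = logging.getLogger("histolearn")

__all__ = [
    "SchedulerConfig",
    "TrainConfig",
    "TrainHistory",
    "ArrayDataset",
    "lr_schedule",
    "train",
    "fine_tune",
    "predict_proba_batched",
    "load_records",
]


@dataclass(frozen=True)
class SchedulerConfig:
    """Stepwise exponential decay between two learning-rate bounds."""

    lr_max: float = 5e-5
    lr_min: float = 1e-5
    decay: float = 0.8

    def __post_init__(self):
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must not exceed lr_max")
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0, 1)")


def lr_schedule(epoch: int, cfg: SchedulerConfig) -> float:
    """lr(e) = max(lr_min, lr_max · decay^e) — non-increasing, bounded."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return max(cfg.lr_min, cfg.lr_max * cfg.decay ** epoch)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    optimizer: str = "adam"
    base_lr: float = 1e-3
    loss: str = "categorical-cross-entropy"
    epochs: int = 1
    freeze_config: FreezeConfig | None = None
    scheduler: SchedulerConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """One row per completed epoch."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


class ArrayDataset:
    """Preloaded labeled images with per-epoch augmentation and mixup.

    Holds normalized H×W×3 images and integer labels; ``batches`` yields
    shuffled (NCHW, one-hot) minibatches, applying geometric augmentation
    per image and mixup per batch when configured. Augmentation draws from
    the generator passed by the trainer, so epochs differ but the whole run
    is reproducible from one seed.
    """

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 augment: AugmentConfig | None = None, mixup: bool = False):
        self.images = np.asarray(images, dtype=np.float32)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images/labels length mismatch")
        self.augment = augment
        self.mixup = mixup

    def __len__(self) -> int:
        return self.images.shape[0]

    def batches(self, batch_size: int, rng: np.random.Generator):
        idx = rng.permutation(len(self))
        n_classes = len(CLASSES)
        for start in range(0, len(idx), batch_size):
            sel = idx[start:start + batch_size]
            imgs = self.images[sel]
            if self.augment is not None:
                from .preprocess import ImageTensor
                imgs = np.stack([
                    standard_augment(ImageTensor(im, normalized=True),
                                     self.augment, rng).pixels
                    for im in imgs])
            onehot = np.eye(n_classes, dtype=np.float32)[self.labels[sel]]
            if self.mixup and len(sel) >= 2 and self.augment is not None:
                imgs, onehot = mixup_batch(imgs, onehot,
                                           alpha=self.augment.mixup_alpha,
                                           seed=int(rng.integers(2 ** 31)))
            yield np.transpose(imgs, (0, 3, 1, 2)), onehot


def load_records(records: list[ImageRecord],
                 resize_to: tuple[int, int] | None = None,
                 crop_to: tuple[int, int] | None = None,
                 mode: str = "center", seed: int = 0) -> np.ndarray:
    """Decode, optionally resize/crop, and standardize a list of records."""
    out = []
    for i, rec in enumerate(records):
        img = load_image(rec.path, provenance=rec.id)
        if resize_to is not None and crop_to is not None:
            img = resize_and_crop(img, resize_to, crop_to, mode=mode,
                                  seed=seed + i)
        out.append(normalize_image(img).pixels)
    return np.stack(out) if out else np.empty((0, 0, 0, 3), dtype=np.float32)


def train(model: ModelGraph, data: ArrayDataset, cfg: TrainConfig,
          optimizer: nn.Adam | None = None,
          ) -> tuple[ModelGraph, TrainHistory]:
    """Train in place for cfg.epochs; only trainable-flagged layers change.

    The per-epoch learning rate is cfg.base_lr, or the scheduler value when
    a scheduler is configured. Raises on empty data and on non-finite loss.
    An existing optimizer may be passed to continue a run without resetting
    Adam's moment estimates (used by the self-training loop).
    """
    if len(data) == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    if not model._initialized:
        model.initialize(cfg.seed)
    opt = optimizer if optimizer is not None else nn.Adam(model.root, lr=cfg.base_lr)
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        lr = (lr_schedule(epoch, cfg.scheduler) if cfg.scheduler is not None
              else cfg.base_lr)
        opt.lr = lr
        losses, hits, seen = [], 0, 0
        for xb, yb in data.batches(cfg.batch_size, rng):
            logits = model.forward_logits(xb, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step()
            losses.append(loss * xb.shape[0])
            hits += int((logits.argmax(1) == yb.argmax(1)).sum())
            seen += xb.shape[0]
        history.append(epoch=epoch, loss=float(np.sum(losses) / seen),
                       accuracy=hits / seen, lr=lr)
    return model, history


def fine_tune(model: ModelGraph, data: ArrayDataset, cfg: TrainConfig,
              ) -> tuple[ModelGraph, TrainHistory]:
    """Apply the freeze configuration, then train with the lr scheduler."""
    if cfg.freeze_config is None:
        raise ValueError("fine_tune requires cfg.freeze_config")
    apply_freeze_config(model, cfg.freeze_config)
    if cfg.scheduler is None:
        cfg = _dc_replace(cfg, scheduler=SchedulerConfig())
    return train(model, data, cfg)


def predict_proba_batched(model: ModelGraph, images: np.ndarray,
                          batch_size: int = 64) -> np.ndarray:
    """Class probabilities for N×H×W×3 images, evaluated in minibatches."""
    if images.shape[0] == 0:
        return np.empty((0, len(CLASSES)), dtype=np.float32)
    chunks = [model.predict_proba(images[i:i + batch_size])
              for i in range(0, images.shape[0], batch_size)]
    return np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ModelGraph, path: str) -> None:
    """Serialize weights plus the architecture spec to one .npz file."""
    import json
    from dataclasses import asdict

    spec_dict = asdict(model.spec)
    arrays = model.get_weights()
    arrays["__spec__"] = np.frombuffer(
        json.dumps(spec_dict).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> ModelGraph:
    import json

    from .architecture import ArchitectureSpec, assemble_model

    data = np.load(path)
    spec_dict = json.loads(bytes(data["__spec__"]).decode())
    for key in ("stages_included", "stage_widths", "blocks_per_stage",
                "input_size"):
        spec_dict[key] = tuple(spec_dict[key])
    if spec_dict["branch_widths"] is not None:
        spec_dict["branch_widths"] = tuple(spec_dict["branch_widths"])
    model = assemble_model(ArchitectureSpec(**spec_dict)).initialize(0)
    for layer in model.root.walk():
        for pname in list(layer.params):
            layer.params[pname] = data[f"{layer.name}/{pname}"].copy()
    return model
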