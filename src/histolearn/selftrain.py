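"""Confidence-thresholded pseudo-label self-training.

The semi-supervised loop: starting from a small labeled pool (by default
20% of the training split, i.e. 16% of all data under an 80/20 split), the
model is trained on the labeled pool, predicts the unlabeled pool, and
every prediction whose confidence — the maximum class probability —
strictly exceeds the threshold (default 0.90) is absorbed into the labeled
pool with its pseudo-label. Pseudo-labels are frozen once assigned; the
test split never enters any training pool. The default schedule is 11
rounds of one epoch each with batch size 16 and learning rate 0.001.

Confidence is computed on center-cropped, unmixed images; mixup and
geometric augmentation apply only while training on the labeled pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .architecture import ModelGraph
from .datamodel import CLASSES, Manifest
from .preprocess import AugmentConfig
from .training import (ArrayDataset, TrainConfig, predict_proba_batched,
                       train)

logger = logging.getLogger("histolearn")

__all__ = [
    "DEFAULT_CONFIDENCE_THRESHOLD",
    "DEFAULT_ROUNDS",
    "PseudoLabelResult",
    "SelfTrainState",
    "PoolData",
    "predict_labels",
    "filter_confident",
    "self_train",
]

DEFAULT_CONFIDENCE_THRESHOLD = 0.90
DEFAULT_ROUNDS = 11


@dataclass
class PseudoLabelResult:
    record_id: str
    predicted_label: str
    confidence: float
    accepted: bool = False


@dataclass
class SelfTrainState:
    """Pools and per-round history of the self-training loop."""

    labeled_ids: list[str]
    unlabeled_ids: list[str]
    test_ids: list[str]
    round: int = 0
    pseudo_label_map: dict[str, str] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.check_invariants()

    @classmethod
    def from_manifest(cls, manifest: Manifest) -> "SelfTrainState":
        return cls(
            labeled_ids=[r.id for r in manifest.select(pool="labeled")],
            unlabeled_ids=[r.id for r in manifest.select(pool="unlabeled")],
            test_ids=[r.id for r in manifest.select(split="test")],
        )

    def check_invariants(self) -> None:
        lab, unlab, test = (set(self.labeled_ids), set(self.unlabeled_ids),
                            set(self.test_ids))
        if lab & unlab or lab & test or unlab & test:
            raise AssertionError("self-training pools are not disjoint")
        if test & (lab | unlab):
            raise AssertionError("test records leaked into a training pool")

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


@dataclass
class PoolData:
    """Preloaded images and ground-truth labels keyed by record id.

    True labels are consulted only for records in the initial labeled pool
    and for test-accuracy bookkeeping; absorbed records train on their
    pseudo-labels.
    """

    images: dict[str, np.ndarray]
    true_labels: dict[str, str]
    augment: AugmentConfig | None = None
    mixup: bool = True

    def stack(self, ids: list[str]) -> np.ndarray:
        if not ids:
            return np.empty((0, 1, 1, 3), dtype=np.float32)
        return np.stack([self.images[i] for i in ids])


def predict_labels(model: ModelGraph, ids: list[str],
                   images: np.ndarray) -> list[PseudoLabelResult]:
    """Model predictions with confidences for a pool of images.

    Confidence is the maximum class probability; an exact tie resolves to
    the first class in index order (benign).
    """
    if len(ids) == 0:
        return []
    proba = predict_proba_batched(model, images)
    pred_idx = proba.argmax(axis=1)   # ties -> first index
    return [PseudoLabelResult(record_id=rid,
                              predicted_label=CLASSES[int(k)],
                              confidence=float(proba[i, k]))
            for i, (rid, k) in enumerate(zip(ids, pred_idx))]


def filter_confident(results: list[PseudoLabelResult],
                     threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                     ) -> list[PseudoLabelResult]:
    """Keep predictions whose confidence strictly exceeds the threshold.

    The strict inequality implements "confidence beyond the threshold": a
    confidence exactly equal to it is rejected. Order is preserved and the
    ``accepted`` flag is set on every input result. A threshold of 0 accepts
    everything (2-class softmax confidences are strictly positive); a
    threshold above 1 is legal and accepts nothing.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    accepted = []
    for r in results:
        r.accepted = r.confidence > threshold
        if r.accepted:
            accepted.append(r)
    return accepted


def self_train(model: ModelGraph, state: SelfTrainState, data: PoolData,
               rounds: int = DEFAULT_ROUNDS, per_round_epochs: int = 1,
               threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
               train_cfg: TrainConfig | None = None,
               initial_epochs: int = 0,
               ) -> tuple[ModelGraph, SelfTrainState]:
    """Run the pseudo-label self-training loop.

    Per round: train on the current labeled pool (augmented, mixup),
    predict the unlabeled pool on unmixed images, absorb predictions above
    the confidence threshold with frozen pseudo-labels, and record history
    (labeled size, accepted count, train and test accuracy). Stops after
    ``rounds`` rounds or once the unlabeled pool is empty; a round that
    accepts nothing is legal and the loop continues.

    ``initial_epochs`` trains the model on the initial labeled pool before
    any pseudo-labeling. The reference protocol starts the loop from a
    pretrained backbone already fitted to the labeled data; a model trained
    from random initialization needs this warm-up, because an unconverged
    softmax classifier emits high-confidence predictions at chance accuracy
    and would poison the pool with frozen wrong pseudo-labels.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not state.labeled_ids:
        raise ValueError("initial labeled pool is empty")
    cfg = train_cfg or TrainConfig()
    if not model._initialized:
        model.initialize(cfg.seed)
    from . import nn
    optimizer = nn.Adam(model.root, lr=cfg.base_lr)

    if initial_epochs > 0:
        labels = [data.true_labels[i] for i in state.labeled_ids]
        y0 = np.array([CLASSES.index(l) for l in labels], dtype=np.int64)
        warm = ArrayDataset(data.stack(state.labeled_ids), y0,
                            augment=data.augment, mixup=data.mixup)
        warm_cfg = TrainConfig(batch_size=cfg.batch_size, base_lr=cfg.base_lr,
                               epochs=initial_epochs, scheduler=cfg.scheduler,
                               seed=cfg.seed)
        train(model, warm, warm_cfg, optimizer=optimizer)

    test_images = data.stack(state.test_ids)
    test_truth = np.array([CLASSES.index(data.true_labels[i])
                           for i in state.test_ids])
    n_total = len(state.labeled_ids) + len(state.unlabeled_ids)

    for rnd in range(rounds):
        state.round = rnd + 1
        labels = [state.pseudo_label_map.get(i, data.true_labels.get(i))
                  for i in state.labeled_ids]
        y = np.array([CLASSES.index(l) for l in labels], dtype=np.int64)
        ds = ArrayDataset(data.stack(state.labeled_ids), y,
                          augment=data.augment, mixup=data.mixup)
        round_cfg = TrainConfig(batch_size=cfg.batch_size, base_lr=cfg.base_lr,
                                epochs=per_round_epochs,
                                scheduler=cfg.scheduler,
                                seed=cfg.seed + 1 + rnd)
        _, hist = train(model, ds, round_cfg, optimizer=optimizer)
        train_acc = hist.epochs[-1]["accuracy"]

        results = predict_labels(model, state.unlabeled_ids,
                                 data.stack(state.unlabeled_ids))
        accepted = filter_confident(results, threshold)
        for r in accepted:
            if r.record_id in state.pseudo_label_map:
                raise AssertionError(f"record {r.record_id} absorbed twice")
            state.pseudo_label_map[r.record_id] = r.predicted_label
        accepted_ids = {r.record_id for r in accepted}
        state.labeled_ids = state.labeled_ids + [r.record_id for r in accepted]
        state.unlabeled_ids = [i for i in state.unlabeled_ids
                               if i not in accepted_ids]

        test_acc = float("nan")
        if len(state.test_ids):
            proba = predict_proba_batched(model, test_images)
            test_acc = float((proba.argmax(1) == test_truth).mean())

        state.check_invariants()
        if len(state.labeled_ids) + len(state.unlabeled_ids) != n_total:
            raise AssertionError("pool conservation violated")
        state.history.append({
            "round": state.round,
            "labeled_size": len(state.labeled_ids),
            "accepted": len(accepted),
            "train_acc": train_acc,
            "test_acc": test_acc,
        })
        logger.info("round %d: labeled=%d accepted=%d train_acc=%.3f "
                    "test_acc=%.3f", state.round, len(state.labeled_ids),
                    len(accepted), train_acc, test_acc)
        if not state.unlabeled_ids:
            break
    return model, state
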