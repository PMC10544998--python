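"""Teacher-student distillation training loop.

Four run modes ablate the objective:

===========  =================================================
``plain``    focal loss only (no teacher)
``logits``   ``(1 - alpha) * L_soft + beta * L_focal``
``feature``  ``alpha * L_feat + beta * L_focal``
``full``     ``alpha * L_feat + (1 - alpha) * L_soft + beta * L_focal``
===========  =================================================

The teacher is supplied already trained; its parameters are never
touched (no gradient is ever computed for it). The student and, in the
feature modes, the four 1x1 channel adapters are optimized jointly with
decoupled-weight-decay Adam. The three loss components are read as one
joint objective, not sequential phases; an optional feature-only warm-up
of a configurable number of epochs accommodates the sequential reading
(default 0).

After every epoch the validation accuracy is measured and the best
checkpoint so far is retained; :func:`restore_best` puts it back into
the model. All randomness derives from the config seed, so identical
configs and data give bitwise-identical loss histories.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import losses, nn
from .backbone import (
    AdapterBank,
    StagedBackbone,
    build_adapters,
    forward_with_features,
    from_meta,
    predict,
)
from .losses import FocalParams, LossWeights

__all__ = [
    "MODES",
    "DistillConfig",
    "TrainingState",
    "train",
    "restore_best",
    "save_checkpoint",
    "load_checkpoint",
    "export_history",
]

MODES = ("plain", "logits", "feature", "full")

logger = logging.getLogger(__name__)


@dataclass
class DistillConfig:
    """Hyperparameters of the objective and the training loop.

    Defaults follow the reference protocol: AdamW with learning rate
    0.001, first-moment decay 0.9, weight decay 5e-4, batch size 32,
    100 epochs, five repeats, loss coefficients alpha = 0.5 and
    beta = 1. The distillation temperature (4) and focusing exponent
    (2) are conventional values; both are freely configurable.
    """

    mode: str = "full"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    focal: FocalParams = field(default_factory=FocalParams)
    learning_rate: float = 0.001
    weight_decay: float = 5e-4
    momentum_beta1: float = 0.9
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    n_repeats: int = 5
    freeze_all_but_head: bool = False
    warmup_epochs: int = 0
    t_squared: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if not 0.0 <= self.momentum_beta1 < 1.0:
            raise ValueError("momentum_beta1 must lie in [0, 1)")
        for name in ("epochs", "batch_size", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be nonnegative")


@dataclass
class TrainingState:
    """Per-epoch loss/metric history and the best-on-validation weights."""

    history: list[dict] = field(default_factory=list)
    best_val_accuracy: float = -1.0
    best_epoch: int = -1
    best_params: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def epoch(self) -> int:
        return len(self.history)


def _validate_inputs(student, teacher, train_data, val_data, config) -> None:
    if config.mode != "plain" and teacher is None:
        raise ValueError(f"mode {config.mode!r} requires a trained teacher")
    for name, (x, y) in (("train", train_data), ("val", val_data)):
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"{name} data is empty")
        if len(x) != len(y):
            raise ValueError(f"{name} images and labels disagree on length")


def _accuracy(model: StagedBackbone, x: np.ndarray, y: np.ndarray, batch: int = 128) -> float:
    hits = 0
    for i in range(0, len(x), batch):
        hits += int(np.sum(predict(model, x[i : i + batch]) == y[i : i + batch]))
    return hits / len(x)


def train(
    student: StagedBackbone,
    teacher: StagedBackbone | None,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: DistillConfig,
    adapters: AdapterBank | None = None,
    batch_transform: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
) -> TrainingState:
    """Optimize the student (and adapters) under the configured mode.

    ``train_data`` / ``val_data`` are ``(images, labels)`` pairs of
    arrays; images are float (N, C, H, W) batches unless a
    ``batch_transform`` is given, in which case training images may be
    raw (N, H, W, C) uint8 arrays that the transform converts (e.g.
    augmentation followed by preprocessing). Validation images are
    always pre-processed floats.

    Returns the :class:`TrainingState`; the student is left with its
    final-epoch weights — use :func:`restore_best` for the
    best-on-validation checkpoint.
    """
    _validate_inputs(student, teacher, train_data, val_data, config)
    w = config.loss_weights
    use_feature = config.mode in ("feature", "full")
    use_soft = config.mode in ("logits", "full")

    if use_feature and adapters is None:
        adapters = build_adapters(student, teacher, seed=config.seed)

    trainable: dict[str, np.ndarray] = {}
    if config.freeze_all_but_head:
        for name, p in student.head.params().items():
            trainable[f"head.{name}"] = p
    else:
        trainable.update(student.params())
    if use_feature:
        trainable.update({f"bank.{k}": v for k, v in adapters.params().items()})

    optimizer = nn.AdamW(
        trainable,
        lr=config.learning_rate,
        betas=(config.momentum_beta1, 0.999),
        eps=1e-8,
        weight_decay=config.weight_decay,
    )

    x_train, y_train = train_data
    y_train = np.asarray(y_train)
    rng = np.random.default_rng(config.seed)
    state = TrainingState()

    for epoch in range(config.epochs):
        warmup = use_feature and epoch < config.warmup_epochs
        order = rng.permutation(len(x_train))
        sums = {"loss1": 0.0, "loss2": 0.0, "loss3": 0.0, "total": 0.0}
        n_seen = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            if batch_transform is not None:
                xb = batch_transform(xb, rng)
            yb = y_train[idx]

            logits, feats = forward_with_features(student, xb)
            l1 = l2 = l3 = 0.0
            g_logits = np.zeros(logits.shape, dtype=float)
            fgrads = agrads = None

            t_logits = t_feats = None
            if teacher is not None and (use_feature or use_soft):
                if use_feature:
                    t_logits, t_feats = forward_with_features(teacher, xb)
                else:
                    t_logits = teacher.forward(xb)

            if use_feature:
                l1, fgrads, agrads = losses.feature_match_loss(
                    feats, t_feats, adapters, return_grads=True
                )
            if use_soft and not warmup:
                l2, g2 = losses.soft_target_loss(
                    logits,
                    t_logits,
                    w.temperature,
                    t_squared=config.t_squared,
                    return_grad=True,
                )
                g_logits += (1.0 - w.alpha) * g2
            if not warmup:
                probs = losses.tempered_softmax(logits, 1.0)
                l3, gp = losses.focal_loss(probs, yb, config.focal, return_grad=True)
                g3 = losses.softmax_backward(probs, gp)
                g_logits += (1.0 if config.mode == "plain" else w.beta) * g3

            if config.mode == "plain":
                total = l3
            elif warmup:
                total = w.alpha * l1
            elif config.mode == "logits":
                total = (1.0 - w.alpha) * l2 + w.beta * l3
            elif config.mode == "feature":
                total = w.alpha * l1 + w.beta * l3
            else:
                total = losses.total_loss(l1, l2, l3, w)

            student.zero_grad()
            if adapters is not None:
                adapters.zero_grad()
            g = student.head.backward(g_logits.astype(nn.DTYPE))
            for k in range(len(student.stages) - 1, -1, -1):
                if use_feature:
                    g = g + (w.alpha * fgrads[k]).astype(nn.DTYPE)
                g = student.stages[k].backward(g)
            if use_feature:
                for k, (gw, gb) in enumerate(agrads):
                    adapters[k].grad_weight += (w.alpha * gw).astype(nn.DTYPE)
                    adapters[k].grad_bias += (w.alpha * gb).astype(nn.DTYPE)

            grads = {}
            if config.freeze_all_but_head:
                for name, gr in student.head.grads().items():
                    grads[f"head.{name}"] = gr
            else:
                grads.update(student.grads())
            if use_feature:
                grads.update({f"bank.{k}": v for k, v in adapters.grads().items()})
            optimizer.step({k: grads[k] for k in trainable})

            nb = len(idx)
            sums["loss1"] += l1 * nb
            sums["loss2"] += l2 * nb
            sums["loss3"] += l3 * nb
            sums["total"] += total * nb
            n_seen += nb

        val_acc = _accuracy(student, *val_data)
        row = {
            "epoch": epoch + 1,
            "loss1": sums["loss1"] / n_seen,
            "loss2": sums["loss2"] / n_seen,
            "loss3": sums["loss3"] / n_seen,
            "total": sums["total"] / n_seen,
            "val_accuracy": val_acc,
        }
        state.history.append(row)
        logger.info(
            "epoch %d/%d mode=%s loss1=%.5f loss2=%.5f loss3=%.5f total=%.5f val_acc=%.4f",
            epoch + 1, config.epochs, config.mode,
            row["loss1"], row["loss2"], row["loss3"], row["total"], val_acc,
        )
        if val_acc > state.best_val_accuracy:
            state.best_val_accuracy = val_acc
            state.best_epoch = epoch + 1
            state.best_params = student.copy_params()
    return state


def restore_best(model: StagedBackbone, state: TrainingState) -> None:
    """Load the best-on-validation weights back into the model."""
    if not state.best_params:
        raise ValueError("training state holds no best checkpoint")
    model.set_params(state.best_params)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path, model: StagedBackbone, extra: dict | None = None
) -> None:
    """Serialize weights + architecture metadata as a NumPy ``.npz``."""
    payload = {f"param::{k}": v for k, v in model.params().items()}
    meta = {"model_meta": model.meta, "extra": extra or {}}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(
    path: str | Path, model: StagedBackbone | None = None
) -> tuple[StagedBackbone, dict]:
    """Load a checkpoint; rebuilds miniature backbones from metadata.

    Pass ``model`` to load weights into an existing (matching)
    architecture instead.
    """
    with np.load(path) as blob:
        meta = json.loads(bytes(blob["meta_json"]).decode("utf-8"))
        params = {
            k.removeprefix("param::"): blob[k]
            for k in blob.files
            if k.startswith("param::")
        }
    if model is None:
        model = from_meta(meta["model_meta"])
    model.set_params(params)
    return model, meta.get("extra", {})


def export_history(state: TrainingState, path: str | Path) -> None:
    """Training history as CSV (epoch, loss1, loss2, loss3, total, val_accuracy)."""
    fields = ["epoch", "loss1", "loss2", "loss3", "total", "val_accuracy"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in state.history:
            writer.writerow(row)
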