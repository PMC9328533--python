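"""SGD training loop with early stopping on validation loss."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from svimon.errors import ParameterError
from svimon.segnet.model import SegModel, image_to_input
from svimon.segnet.nn import softmax_cross_entropy

__all__ = ["TrainConfig", "TrainHistory", "train_model", "pairs_to_arrays"]


@dataclass(frozen=True)
class TrainConfig:
    """Published training hyperparameters with desk-scale escape hatches.

    ``nms_threshold`` is retained from the reference configuration for
    fidelity but has no role in semantic segmentation and is never used.
    """

    batch_size: int = 16
    learning_rate: float = 0.0001
    loss: str = "categorical_crossentropy"
    optimizer: str = "sgd"
    momentum: float = 0.9
    clip_norm: float = 5.0  # global gradient-norm ceiling; 0 disables
    max_epochs: int = 200
    early_stop_patience: int = 15
    nms_threshold: float = 0.45  # recorded, unused (no detection stage)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.learning_rate <= 0 or self.max_epochs < 1:
            raise ParameterError("batch_size, learning_rate, max_epochs must be positive")
        if not (0 < self.early_stop_patience < self.max_epochs):
            raise ParameterError("patience must be positive and < max_epochs")
        if self.loss != "categorical_crossentropy":
            raise ParameterError(f"unsupported loss '{self.loss}'")
        if self.optimizer != "sgd":
            raise ParameterError(f"unsupported optimizer '{self.optimizer}'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": i + 1,
                "train_loss": self.train_loss[i],
                "val_loss": self.val_loss[i],
                "train_acc": self.train_acc[i],
                "val_acc": self.val_acc[i],
            }
            for i in range(self.stopped_epoch)
        ]


def pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Scene pairs -> (X, Y): (N,3,H,W) float32 in [0,1] and (N,H,W) int64."""
    xs = [image_to_input(p.image)[0] for p in pairs]
    ys = [np.asarray(p.mask, dtype=np.int64) for p in pairs]
    return np.stack(xs), np.stack(ys)


def _evaluate(model: SegModel, x: np.ndarray, y: np.ndarray, batch: int) -> tuple[float, float]:
    losses, correct, total = [], 0, 0
    for i in range(0, len(x), batch):
        xb, yb = x[i : i + batch], y[i : i + batch]
        logits = model.forward(xb, train=False)
        loss, _, probs = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        pred = probs.argmax(axis=1)
        correct += int((pred == yb).sum())
        total += yb.size
    return float(np.sum(losses) / len(x)), correct / total


def train_model(
    model: SegModel,
    train_pairs,
    val_pairs,
    config: TrainConfig = TrainConfig(),
) -> tuple[SegModel, TrainHistory]:
    """Mini-batch SGD (with momentum) on categorical cross-entropy.

    Stops at ``max_epochs`` or when the validation loss has not improved for
    ``early_stop_patience`` consecutive epochs; the returned model carries
    the best-validation-loss weights. Reproducible for a fixed seed.
    """
    if not train_pairs or not val_pairs:
        raise ParameterError("train and validation sets must be non-empty")
    x_tr, y_tr = pairs_to_arrays(train_pairs)
    x_va, y_va = pairs_to_arrays(val_pairs)

    rng = np.random.default_rng(config.seed)
    velocity = [np.zeros_like(p) for p, _ in model.params()]
    history = TrainHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    since_improve = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_correct, ep_total = 0.0, 0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            if config.clip_norm > 0:
                gnorm = np.sqrt(sum(float((g * g).sum()) for _, g in model.params()))
                if gnorm > config.clip_norm:
                    scale = config.clip_norm / gnorm
                    for _, g in model.params():
                        g *= scale
            for v, (p, g) in zip(velocity, model.params()):
                v *= config.momentum
                v -= config.learning_rate * g
                p += v
            ep_loss += loss * len(xb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            ep_total += yb.size

        val_loss, val_acc = _evaluate(model, x_va, y_va, config.batch_size)
        history.train_loss.append(ep_loss / len(x_tr))
        history.train_acc.append(ep_correct / ep_total)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.stopped_epoch = epoch + 1

        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch + 1
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.early_stop_patience:
                break

    model.set_weights(best_weights)
    return model, history
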