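"""Dataset splitting, the training policy, the optimizer loop and metrics.

Training policy: Adam, initial learning rate 0.01, shrunk by 10x at
epochs 20 and 40, 50 epochs, batch size 128, classic L2 penalty on the
convolution weights.  Validation data is only monitored, never used for
stopping.  Everything is reproducible from the policy seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .network import EMGNet, forward

__all__ = [
    "TrainPolicy",
    "DatasetSplit",
    "Metrics",
    "split_dataset",
    "lr_at_epoch",
    "train",
    "evaluate",
    "confusion_matrix",
]


@dataclass(frozen=True)
class TrainPolicy:
    optimizer: str = "adam"
    initial_lr: float = 0.01
    lr_milestones: tuple[int, ...] = (20, 40)
    lr_factor: float = 0.1
    epochs: int = 50
    batch_size: int = 128
    weight_decay: float = 1e-2  # classic L2 coefficient
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if any(not 1 <= m <= self.epochs for m in self.lr_milestones):
            raise ValueError(
                f"lr milestones {self.lr_milestones} must lie in [1, {self.epochs}]"
            )
        if self.initial_lr <= 0 or not 0 < self.lr_factor <= 1:
            raise ValueError("invalid learning-rate settings")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DatasetSplit:
    """Per-class disjoint, exhaustive train/val/test index lists."""

    train: dict
    val: dict
    test: dict
    fractions: tuple[float, float, float]
    seed: int

    def indices(self, part: str) -> np.ndarray:
        d = getattr(self, part)
        if not d:
            return np.array([], dtype=int)
        return np.concatenate([np.asarray(d[k], dtype=int) for k in sorted(d)])


@dataclass
class Metrics:
    accuracy: float  # percent
    per_class_accuracy: dict
    confusion: np.ndarray  # rows true, columns predicted
    classes: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_accuracy": {
                str(k): v for k, v in self.per_class_accuracy.items()
            },
            "confusion": self.confusion.tolist(),
            "classes": [str(c) for c in self.classes],
        }


def split_dataset(
    labels,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded per-class shuffle, then a 60/10/30 cut of each class.

    Rounding rule: the train and validation counts are floored, the test
    set takes the remaining tail of the shuffled order.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = {}, {}, {}
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(
                f"class {cls!r} has only {idx.size} samples; need >= 3"
            )
        idx = idx[rng.permutation(idx.size)]
        n_train = int(np.floor(fractions[0] * idx.size))
        n_val = int(np.floor(fractions[1] * idx.size))
        train[cls] = idx[:n_train]
        val[cls] = idx[n_train : n_train + n_val]
        test[cls] = idx[n_train + n_val :]
    return DatasetSplit(train=train, val=val, test=test,
                        fractions=tuple(fractions), seed=seed)


def lr_at_epoch(policy: TrainPolicy, epoch: int) -> float:
    """Step-decayed learning rate; the decay applies AT each milestone."""
    if not 1 <= epoch <= policy.epochs:
        raise ValueError(f"epoch {epoch} outside [1, {policy.epochs}]")
    n_decays = sum(1 for m in policy.lr_milestones if epoch >= m)
    return policy.initial_lr * policy.lr_factor**n_decays


def _batched_logits(model: EMGNet, x: np.ndarray, batch: int = 256) -> np.ndarray:
    return np.concatenate(
        [forward(model, x[i : i + batch]) for i in range(0, x.shape[0], batch)]
    )


def _loss_acc(model: EMGNet, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits = _batched_logits(model, x)
    loss, _ = nn.softmax_cross_entropy(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train(
    model: EMGNet,
    split: DatasetSplit,
    tensors: np.ndarray,
    labels,
    policy: TrainPolicy = TrainPolicy(),
) -> dict:
    """Minimize the cross-entropy plus L2 penalty with Adam.

    ``labels`` must be integer class indices in ``[0, n_classes)``.
    Batches are drawn with per-epoch reshuffling; the last short batch is
    kept.  Returns a per-epoch history dict (losses, accuracies, learning
    rate, optimizer step count).
    """
    tensors = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=int)
    train_idx = split.indices("train")
    if train_idx.size == 0:
        raise ValueError("empty training set")
    val_idx = split.indices("val")
    rng = np.random.default_rng(policy.seed)
    optimizer = nn.Adam(model.graph)
    history = {
        "epoch": [], "lr": [], "train_loss": [], "train_acc": [],
        "val_loss": [], "val_acc": [], "steps": [],
    }
    for epoch in range(1, policy.epochs + 1):
        lr = lr_at_epoch(policy, epoch)
        order = train_idx[rng.permutation(train_idx.size)]
        epoch_loss, n_steps = 0.0, 0
        for start in range(0, order.size, policy.batch_size):
            batch_idx = order[start : start + policy.batch_size]
            xb, yb = tensors[batch_idx], y[batch_idx]
            logits = forward(model, xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            loss += model.graph.l2_penalty(policy.weight_decay)
            model.graph.zero_grad()
            model.graph.backward(dlogits)
            model.graph.add_l2_grads(policy.weight_decay)
            optimizer.step(lr)
            epoch_loss += loss * len(batch_idx)
            n_steps += 1
        train_loss, train_acc = _loss_acc(model, tensors[train_idx], y[train_idx])
        if val_idx.size:
            val_loss, val_acc = _loss_acc(model, tensors[val_idx], y[val_idx])
        else:
            val_loss = val_acc = float("nan")
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(train_loss)
        history["train_acc"].append(train_acc)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["steps"].append(n_steps)
    return history


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Rows are true classes, columns predicted classes."""
    classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes.tolist())}
    mat = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(np.asarray(y_true).tolist(), np.asarray(y_pred).tolist()):
        mat[index[t], index[p]] += 1
    return mat


def evaluate(model: EMGNet, tensors: np.ndarray, labels) -> Metrics:
    """Overall accuracy (%), per-class accuracy and the confusion matrix."""
    tensors = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty test set")
    preds = _batched_logits(model, tensors).argmax(axis=1)
    classes = np.arange(model.config.n_classes)
    mat = confusion_matrix(y, preds, classes)
    accuracy = 100.0 * float(np.trace(mat)) / float(mat.sum())
    per_class = {}
    for i, cls in enumerate(classes.tolist()):
        total = mat[i].sum()
        per_class[cls] = 100.0 * mat[i, i] / total if total else float("nan")
    return Metrics(
        accuracy=accuracy, per_class_accuracy=per_class,
        confusion=mat, classes=classes,
    )
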