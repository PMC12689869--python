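"""Composite segmentation training loss: cross-entropy plus soft Dice.

The Dice term is ``1 - mean soft Dice over foreground classes`` so that the
quantity being minimized actually decreases as overlap improves; background
is excluded to keep the term sensitive under heavy class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor

__all__ = ["LossValue", "cross_entropy_loss", "soft_dice_loss", "total_loss",
           "total_loss_tensor"]

LOG_EPS = 1e-7
DICE_SMOOTH = 1e-5


@dataclass
class LossValue:
    total: float
    ce: float
    dice: float

    def __post_init__(self):
        for v in (self.total, self.ce, self.dice):
            if not np.isfinite(v) or v < -1e-12:
                raise ValueError(f"loss components must be finite and non-negative, got {self}")


def _check_labels(labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(
            f"labels must lie in [0, {num_classes}), got range "
            f"[{labels.min()}, {labels.max()}]")
    return labels.astype(np.int64)


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    return np.moveaxis(np.eye(num_classes)[labels], -1, 1)


def _ce_tensor(probs: Tensor, labels: np.ndarray) -> Tensor:
    num_classes = probs.shape[1]
    labels = _check_labels(labels, num_classes)
    onehot = _one_hot(labels, num_classes)
    logp = probs.clip_min(LOG_EPS).log()
    return -(logp * onehot).sum() * (1.0 / labels.size)


def _dice_tensor(probs: Tensor, labels: np.ndarray) -> Tensor:
    num_classes = probs.shape[1]
    labels = _check_labels(labels, num_classes)
    onehot = _one_hot(labels, num_classes)
    dice_sum = None
    fg = range(1, num_classes)
    for c in fg:
        p = probs.slice((slice(None), c))
        y = Tensor(onehot[:, c])
        inter = (p * y).sum()
        denom = p.sum() + y.sum() + DICE_SMOOTH
        d = (inter * 2.0 + DICE_SMOOTH) / denom
        dice_sum = d if dice_sum is None else dice_sum + d
    mean_dice = dice_sum * (1.0 / len(list(fg)))
    return 1.0 - mean_dice


def cross_entropy_loss(probs, labels) -> float:
    """Mean negative log-probability of the true class; probabilities are
    clamped at 1e-7 before the log."""
    t = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    return float(_ce_tensor(t, labels).data)


def soft_dice_loss(probs, labels) -> float:
    """1 - mean soft Dice over the foreground classes (smoothing 1e-5)."""
    t = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    return float(_dice_tensor(t, labels).data)


def total_loss(probs, labels) -> LossValue:
    ce = cross_entropy_loss(probs, labels)
    dice = soft_dice_loss(probs, labels)
    return LossValue(total=ce + dice, ce=ce, dice=dice)


def total_loss_tensor(probs: Tensor, labels) -> tuple[Tensor, LossValue]:
    """Differentiable total loss plus a float component record for logging."""
    ce = _ce_tensor(probs, labels)
    dice = _dice_tensor(probs, labels)
    tot = ce + dice
    return tot, LossValue(total=float(tot.data), ce=float(ce.data), dice=float(dice.data))
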