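"""Segmentation losses: binary cross-entropy, Dice, and their weighted sum.

All three accept autodiff tensors (for training) or plain arrays and
reduce to a scalar:

    L_bce  = mean[ (y - 1) log(1 - p) - y log p ]          (standard BCE)
    L_dice = 1 - (2 * sum(y p) + 1) / (sum y + sum p + 1)  (+1 smoothing)
    L      = lambda1 * L_bce + lambda2 * L_dice

Probabilities are clamped to [eps, 1 - eps] before the logarithms.
The default weights are lambda1 = lambda2 = 0.5.
"""

from __future__ import annotations

import dataclasses

from .nn import tensor as T
from .nn.tensor import Tensor


@dataclasses.dataclass
class LossWeights:
    lambda1: float = 0.5
    lambda2: float = 0.5
    epsilon_clamp: float = 1e-7

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")


def _pair(yhat, y) -> tuple[Tensor, Tensor]:
    yhat = yhat if isinstance(yhat, Tensor) else Tensor(yhat)
    y = y if isinstance(y, Tensor) else Tensor(y)
    if yhat.shape != y.shape:
        raise ValueError(f"prediction shape {yhat.shape} != target shape {y.shape}")
    return yhat, y


def bce_loss(yhat, y, eps: float = 1e-7) -> Tensor:
    """Pixel-mean binary cross-entropy on probabilities."""
    yhat, y = _pair(yhat, y)
    p = T.clip(yhat, eps, 1.0 - eps)
    return T.tmean((y - 1.0) * T.log(1.0 - p) - y * T.log(p))


def dice_loss(yhat, y) -> Tensor:
    """Soft Dice loss with +1 smoothing in numerator and denominator."""
    yhat, y = _pair(yhat, y)
    inter = T.tsum(y * yhat)
    total = T.tsum(y) + T.tsum(yhat)
    return 1.0 - (2.0 * inter + 1.0) / (total + 1.0)


def combined_loss(yhat, y, weights: LossWeights | None = None) -> Tensor:
    """lambda1 * BCE + lambda2 * Dice (defaults 0.5 / 0.5)."""
    w = weights if weights is not None else LossWeights()
    return w.lambda1 * bce_loss(yhat, y, w.epsilon_clamp) \
        + w.lambda2 * dice_loss(yhat, y)
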