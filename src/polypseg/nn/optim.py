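"""SGD with momentum and decoupled handling of norm parameters.

Weight decay is applied only to convolution / linear weights; the scale
and shift parameters of normalisation layers (and all biases) are
excluded, the standard convention for segmentation training.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, NORM_TYPES
from .tensor import Tensor


def split_decay_params(model: Module) -> tuple[list[Tensor], list[Tensor]]:
    """Partition parameters into (decayed, undecayed) groups."""
    decay: list[Tensor] = []
    no_decay: list[Tensor] = []
    for _, mod in model.named_modules():
        for name, p in mod._params.items():
            if isinstance(mod, NORM_TYPES) or name == "bias":
                no_decay.append(p)
            else:
                decay.append(p)
    return decay, no_decay


class SGD:
    """Classic momentum SGD: v <- mu*v + g; p <- p - lr*(v + wd*p)."""

    def __init__(self, model: Module, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.momentum = momentum
        decay, no_decay = split_decay_params(model)
        self.groups = [
            {"params": decay, "weight_decay": weight_decay},
            {"params": no_decay, "weight_decay": 0.0},
        ]
        self._velocity = {id(p): np.zeros_like(p.data)
                          for g in self.groups for p in g["params"]}

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        for g in self.groups:
            wd = g["weight_decay"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad
                if wd:
                    grad = grad + wd * p.data
                v = self._velocity[id(p)]
                v *= self.momentum
                v += grad
                p.data = p.data - self.lr * v
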