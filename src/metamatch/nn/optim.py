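"""Stochastic gradient descent with momentum, L2 weight decay and step LR decay."""

from __future__ import annotations


class SGD:
    """Updates the parameters of the given layers in place.

    velocity ← momentum·velocity − lr·(grad + weight_decay·param);
    param ← param + velocity. Batch-norm parameters are exempt from weight
    decay, as is conventional.
    """

    def __init__(self, layers, lr: float = 1e-2, momentum: float = 0.9,
                 weight_decay: float = 1e-3, lr_decay: float = 0.5,
                 lr_step: int = 10) -> None:
        self.layers = list(layers)
        self.base_lr = lr
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_decay = lr_decay
        self.lr_step = lr_step
        self._velocity = [
            {name: 0.0 for name in layer.params} for layer in self.layers
        ]

    def set_epoch(self, epoch: int) -> None:
        if self.lr_step > 0:
            self.lr = self.base_lr * self.lr_decay ** (epoch // self.lr_step)

    def step(self) -> None:
        from .layers import BatchNorm

        for layer, vel in zip(self.layers, self._velocity):
            wd = 0.0 if isinstance(layer, BatchNorm) else self.weight_decay
            for name, param in layer.params.items():
                grad = layer.grads[name] + wd * param
                vel[name] = self.momentum * vel[name] - self.lr * grad
                layer.params[name] = param + vel[name]
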