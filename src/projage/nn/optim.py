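"""Adam optimizer over named parameter slots."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias-corrected first/second moment estimates.

    ``slots`` is a list of (name, layer, param_key) triples as produced by
    ``Sequential.named_params``; the optimizer updates ``layer.params[key]``
    in place from ``layer.grads[key]``.
    """

    def __init__(self, slots, lr: float = 0.003, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = list(slots)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {name: np.zeros_like(layer.params[key]) for name, layer, key in self.slots}
        self._v = {name: np.zeros_like(layer.params[key]) for name, layer, key in self.slots}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, layer, key in self.slots:
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * g
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * (g * g)
            layer.params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
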