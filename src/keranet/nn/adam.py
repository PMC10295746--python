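"""Adam optimizer (Kingma & Ba) with a mutable learning rate."""

from __future__ import annotations

import numpy as np


class Adam:
    """First-order adaptive optimizer.

    Only the learning rate is exposed for scheduling; the moment decay
    rates and epsilon are the customary framework defaults.
    """

    def __init__(self, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for param in params:
            key = id(param)
            if key not in self._m:
                self._m[key] = np.zeros_like(param.value)
                self._v[key] = np.zeros_like(param.value)
            m = self._m[key]
            v = self._v[key]
            m *= b1
            m += (1 - b1) * param.grad
            v *= b2
            v += (1 - b2) * param.grad ** 2
            mhat = m / bias1
            vhat = v / bias2
            param.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
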