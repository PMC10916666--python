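"""Adam optimizer (Kingma & Ba) for engine tensors."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < beta1 < 1 and 0 < beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def add_params(self, params) -> None:
        """Register late-constructed parameters (e.g. lazily built MLPs)."""
        for p in params:
            self.params.append(p)
            self._m.append(np.zeros_like(p.data))
            self._v.append(np.zeros_like(p.data))

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
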