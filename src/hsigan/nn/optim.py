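"""Adam optimizer over the flat named-parameter dicts exposed by layers."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with optional decoupled L2 penalty (added to the raw gradient).

    ``skip`` names parameter suffixes that are state, not trainable weights
    (batch-norm running statistics).
    """

    SKIP_SUFFIXES = ("running_mean", "running_var")

    def __init__(self, lr: float, betas=(0.5, 0.999), eps: float = 1e-8,
                 l2: float = 0.0):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = l2
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for name, p in params.items():
            if name.endswith(self.SKIP_SUFFIXES):
                continue
            g = grads.get(name)
            if g is None:
                continue
            if self.l2 and not name.endswith(("b", "beta", "gamma")):
                g = g + self.l2 * p
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
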