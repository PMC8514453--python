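"""Stochastic-gradient optimizer used by the variational and geodesic fits."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adaptive-moment gradient ascent/descent over a dict of numpy arrays."""

    def __init__(self, params: dict, lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = {k: np.asarray(v, dtype=float).copy() for k, v in params.items()}
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    def step(self, grads: dict):
        """Apply one descent step along `grads` (pass -grad to ascend)."""
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if g is None:
                continue
            g = np.asarray(g, dtype=float)
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1 ** self._t)
            vhat = self._v[k] / (1 - b2 ** self._t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
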