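"""Decoupled-weight-decay Adam (AdamW) over autodiff parameters."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["AdamW"]


class AdamW:
    """AdamW with the standard bias-corrected moment estimates.

    Parameters whose ``grad`` is ``None`` after a backward pass are skipped
    entirely (no moment update, no weight decay), so a loss that never touches
    a parameter leaves it bit-identical.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.98,
        eps: float = 1e-8,
        weight_decay: float = 0.0005,
    ):
        if lr <= 0 or not (0 <= beta1 < 1) or not (0 <= beta2 < 1) or eps <= 0:
            raise ValueError("invalid AdamW hyperparameters")
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self, lr: float | None = None) -> None:
        """Apply one update; ``lr`` overrides the base rate (for schedules)."""
        rate = self.lr if lr is None else lr
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            p.data -= rate * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
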