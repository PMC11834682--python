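"""Adam optimiser over named :class:`~degradict.nn.layers.Param` lists."""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

from .layers import Param


class Adam:
    """Adam with bias correction (default moments beta1=0.9, beta2=0.999).

    The learning rate is passed to every :meth:`step`, so an external
    schedule (e.g. warmup / inverse-square-root decay) owns it.
    """

    def __init__(
        self,
        params: Iterable[Tuple[str, Param]],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params: List[Tuple[str, Param]] = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: Dict[str, np.ndarray] = {
            name: np.zeros_like(p.value) for name, p in self.params
        }
        self.v: Dict[str, np.ndarray] = {
            name: np.zeros_like(p.value) for name, p in self.params
        }

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for name, p in self.params:
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()
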