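"""Layer objects over the autograd core: parameter containers with forward().

Initialization is He-style for convolution weights (ReLU networks), drawn
from a caller-supplied generator so that model construction is fully
deterministic under a seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Minimal parameter-tree container."""

    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def add_module(self, name: str, mod: "Module") -> "Module":
        self._children[name] = mod
        return mod

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, child in self._children.items():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            arr = state[prefix + k]
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {prefix + k}")
            v.data = arr.astype(np.float32).copy()
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
        for name, child in self._children.items():
            child.load_state_dict(state, prefix + name + ".")


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self._params["weight"] = ag.parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self._params["bias"] = ag.parameter(np.zeros(out_channels))
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"Conv2d expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        return ag.conv2d(x, self._params["weight"], self._params["bias"])


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self._params["gamma"] = ag.parameter(np.ones(channels))
        self._params["beta"] = ag.parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
        return ag.batchnorm2d(
            x,
            self._params["gamma"],
            self._params["beta"],
            self._buffers["running_mean"],
            self._buffers["running_var"],
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
            mask=mask,
        )


class Adam:
    """Adam optimizer with decoupled state per parameter."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
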