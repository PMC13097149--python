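"""Layer/module abstractions with explicit rng-seeded initialization."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class: tracks parameters and sub-modules by attribute."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for k, v in self._params.items():
            yield prefix + k, v
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, v in state.items():
            arr = np.asarray(v, dtype=np.float32)
            if arr.shape != own[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k].data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: Optional[int] = None, bias: bool = True):
        super().__init__()
        if pad is None:
            pad = k // 2
        self.stride, self.pad = stride, pad
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / nin)
        self.weight = Tensor(rng.normal(0.0, std, (nin, nout)), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1)
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.k)


class Dropout(Module):
    """Dropout whose noise source is supplied per-forward for determinism."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor, rng: Optional[np.random.Generator] = None) -> Tensor:
        return F.dropout(x, self.p, rng, self.training and self.p > 0)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods: List[Module] = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
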