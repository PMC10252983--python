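"""Layer building blocks on top of the autograd core.

Conventions follow common segmentation-network practice: 3x3 convolutions
are bias-free when immediately followed by batch normalization, He-normal
weight initialization, batch-norm momentum 0.1.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d_s2

__all__ = ["Module", "ModuleList", "Conv2d", "ConvTranspose2x2", "BatchNorm2d",
           "DoubleConv"]


class Module:
    """Base class with parameter/submodule registration and state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, (Module, ModuleList)):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        out.update({k: v.copy() for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value, dtype=params[key].data.dtype)
            else:
                obj, _, leaf = self._locate(key)
                obj._buffers[leaf] = np.asarray(value)
                object.__setattr__(obj, leaf, obj._buffers[leaf])

    def _locate(self, dotted: str):
        parts = dotted.split(".")
        obj = self
        for p in parts[:-1]:
            obj = obj._modules[p] if p in obj._modules else getattr(obj, p)
        return obj, parts, parts[-1]

    def train(self) -> "Module":
        self._set_training(True)
        return self

    def eval(self) -> "Module":
        self._set_training(False)
        return self

    def _set_training(self, flag: bool) -> None:
        object.__setattr__(self, "training", flag)
        for m in self._modules.values():
            m._set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def modules(self):
        """All submodules, depth-first, including self."""
        yield self
        for m in self._modules.values():
            if isinstance(m, ModuleList):
                for item in m:
                    yield from item.modules()
            else:
                yield from m.modules()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList:
    def __init__(self, modules=()):
        self._items: list[Module] = list(modules)

    def append(self, m: Module) -> None:
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._items):
            yield from m.named_parameters(f"{prefix}{i}.")

    def named_buffers(self, prefix: str = ""):
        for i, m in enumerate(self._items):
            yield from m.named_buffers(f"{prefix}{i}.")

    def _set_training(self, flag: bool) -> None:
        for m in self._items:
            m._set_training(flag)

    def _modules_dict(self):
        return {str(i): m for i, m in enumerate(self._items)}

    @property
    def _modules(self):
        return self._modules_dict()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True,
                 dtype=np.float32):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)).astype(dtype)
        )
        if bias:
            self.bias = Tensor(np.zeros(out_ch, dtype=dtype))
        else:
            object.__setattr__(self, "bias", None)
        self.kernel = kernel
        self.padding = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution for learned upsampling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(in_ch, out_ch, 2, 2)).astype(dtype)
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d_s2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.weight = Tensor(np.ones(channels, dtype=dtype))
        self.bias = Tensor(np.zeros(channels, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(channels, dtype=dtype))
        self.register_buffer("running_var", np.ones(channels, dtype=dtype))
        self.eps = eps
        self.momentum = momentum
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.weight, self.bias
        c = self.channels
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (mu.astype(rm.dtype) - rm)
            rv += self.momentum * (var.astype(rv.dtype) - rv)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
        out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
        training = self.training

        def grad_fn(g):
            gg = gamma.data.reshape(1, c, 1, 1)
            ggamma = (g * xhat).sum(axis=(0, 2, 3))
            gbeta = g.sum(axis=(0, 2, 3))
            if training:
                dxhat = g * gg
                m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = inv_std.reshape(1, c, 1, 1) * (dxhat - m1 - xhat * m2)
            else:
                gx = g * gg * inv_std.reshape(1, c, 1, 1)
            return (gx.astype(x.data.dtype), ggamma.astype(gamma.data.dtype),
                    gbeta.astype(beta.data.dtype))

        return Tensor(out.astype(x.data.dtype), (x, gamma, beta), grad_fn)


class DoubleConv(Module):
    """(conv3x3 -> BN -> ReLU) applied twice; the standard encoder/decoder
    block of U-shaped segmentation networks."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 mid_ch: int | None = None):
        super().__init__()
        mid_ch = mid_ch or out_ch
        self.conv1 = Conv2d(in_ch, mid_ch, 3, rng, bias=False)
        self.bn1 = BatchNorm2d(mid_ch)
        self.conv2 = Conv2d(mid_ch, out_ch, 3, rng, bias=False)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()
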