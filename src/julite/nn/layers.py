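"""Layer/module system: Conv2d, BatchNorm2d, Linear, containers.

Modules auto-register child modules and parameters through attribute
assignment (the convention familiar from the mainstream deep-learning
frameworks), so `parameters()`, `state_dict()` and mode switching work on
arbitrary compositions.  Parameter initialization draws from a module-level
RNG; call :func:`manual_seed` before construction for reproducible builds.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor, no_grad

_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the RNG used for parameter initialization."""
    global _rng
    _rng = np.random.default_rng(seed)


DEFAULT_DTYPE = np.float64


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "_forward_hooks", [])

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def modules(self):
        for _, m in self.named_modules():
            yield m

    def named_parameters(self, prefix: str = ""):
        for name, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{name}.{pname}" if name else pname), p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data
        for mname, mod in self.named_modules():
            for bname, buf in mod._buffers.items():
                out[(f"{mname}.{bname}" if mname else bname)] = buf
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = {}
        for mname, mod in self.named_modules():
            for bname in mod._buffers:
                buffers[(f"{mname}.{bname}" if mname else bname)] = (mod, bname)
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.array(value, dtype=params[key].data.dtype)
            elif key in buffers:
                mod, bname = buffers[key]
                mod.register_buffer(bname, np.array(value))
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def astype(self, dtype):
        """Cast all parameters and buffers in place (e.g. float32 training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for mod in self.modules():
            for bname, buf in list(mod._buffers.items()):
                if np.issubdtype(buf.dtype, np.floating):
                    mod.register_buffer(bname, buf.astype(dtype))
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def add_forward_hook(self, fn):
        self._forward_hooks.append(fn)
        return fn

    def clear_forward_hooks(self):
        self._forward_hooks.clear()

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        for hook in self._forward_hooks:
            hook(self, out)
        return out

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._order = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._order.append(m)

    def __iter__(self):
        return iter(self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return self._order[i]

    def forward(self, x):
        for m in self._order:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class ReLU6(Module):
    def forward(self, x):
        return x.relu6()


class HSwish(Module):
    def forward(self, x):
        return F.hswish(x)


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Conv2d(Module):
    """Grouped 2-D convolution; `padding=None` means 'same' for stride 1
    (the usual (K-1)/2 symmetric padding)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = (kernel_size - 1) // 2 if padding is None else padding
        self.groups = groups
        fan_in = in_channels // groups * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(_rng.normal(
            0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size)
        ).astype(DEFAULT_DTYPE))
        if bias:
            self.bias = Parameter(np.zeros(out_channels, dtype=DEFAULT_DTYPE), decay=False)
        else:
            self.bias = None
        self.last_output_hw: tuple[int, int] | None = None

    def forward(self, x):
        out = F.conv2d(x, self.weight, self.bias,
                       stride=(self.stride, self.stride),
                       padding=(self.padding, self.padding),
                       groups=self.groups)
        self.last_output_hw = out.shape[2:]
        return out

    def macs(self) -> int:
        """Multiply-accumulates of the most recent forward (per sample)."""
        if self.last_output_hw is None:
            raise RuntimeError("run a forward pass before counting MACs")
        ho, wo = self.last_output_hw
        k = self.kernel_size
        return k * k * (self.in_channels // self.groups) * self.out_channels * ho * wo


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=DEFAULT_DTYPE), decay=False)
        self.bias = Parameter(np.zeros(num_features, dtype=DEFAULT_DTYPE), decay=False)
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DEFAULT_DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DEFAULT_DTYPE))

    def forward(self, x):
        if self.training:
            out, mu, var, n = F.batch_norm(x, self.weight, self.bias, self.eps)
            m = self.momentum
            unbiased = var * (n / max(n - 1, 1))
            self.register_buffer("running_mean",
                                 (1 - m) * self.running_mean + m * mu)
            self.register_buffer("running_var",
                                 (1 - m) * self.running_var + m * unbiased)
            return out
        scale = (self.running_var + self.eps) ** -0.5
        w = Tensor((self.weight.data * scale)[None, :, None, None])
        b = Tensor((self.bias.data - self.running_mean * self.weight.data
                    * scale)[None, :, None, None])
        # eval mode: running stats folded into a constant affine map
        return x * w + b


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        std = float(np.sqrt(1.0 / in_features))
        self.weight = Parameter(_rng.normal(
            0.0, std, (out_features, in_features)).astype(DEFAULT_DTYPE))
        if bias:
            self.bias = Parameter(np.zeros(out_features, dtype=DEFAULT_DTYPE), decay=False)
        else:
            self.bias = None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)

    def macs(self) -> int:
        return self.in_features * self.out_features
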