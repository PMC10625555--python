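"""Layer objects on top of the autodiff primitives.

Parameters are initialized from a uniform distribution with fan-in scaled
bounds, drawn from a caller-supplied :class:`numpy.random.Generator` so that
a network build is a pure function of (config, seed).
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    conv3d,
    conv3d_down2,
    conv3d_k1,
    conv_transpose3d_up2,
    instance_norm,
)

_F32 = np.float32


def _uniform_fanin(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in)
    t = Tensor(rng.uniform(-bound, bound, size=shape).astype(_F32))
    t.requires_grad = True
    return t


class Module:
    """Base class: parameter registry and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_child(self, name: str, module: "Module"):
        self._children[name] = module
        object.__setattr__(self, name, module)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for c in self._children.values():
            c.train()
        return self

    def eval(self):
        self.training = False
        for c in self._children.values():
            c.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(_F32).copy()


class Conv3d(Module):
    """3D convolution; kernel 3 (pad 1), 2 (stride 2) or 1 are supported."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in = cin * kernel**3
        if kernel == 1:
            self.weight = _uniform_fanin(rng, (cout, cin), fan_in)
        else:
            self.weight = _uniform_fanin(rng, (cout, cin, kernel, kernel, kernel), fan_in)
        self.bias = _uniform_fanin(rng, (cout,), fan_in)

    def __call__(self, x: Tensor) -> Tensor:
        if self.kernel == 3:
            return conv3d(x, self.weight, self.bias)
        if self.kernel == 1:
            return conv3d_k1(x, self.weight, self.bias)
        if self.kernel == 2:
            return conv3d_down2(x, self.weight, self.bias)
        raise ValueError(f"unsupported kernel {self.kernel}")


class ConvTranspose3d(Module):
    """Kernel-2 stride-2 transposed convolution (doubles each spatial axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _uniform_fanin(rng, (cin, cout, 2, 2, 2), cin)
        self.bias = _uniform_fanin(rng, (cout,), cin)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose3d_up2(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, channels: int):
        super().__init__()
        g = Tensor(np.ones(channels, dtype=_F32))
        g.requires_grad = True
        b = Tensor(np.zeros(channels, dtype=_F32))
        b.requires_grad = True
        self.gamma = g
        self.beta = b

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class BatchNorm3d(Module):
    """Batch normalization for the implicit batch of one.

    In training mode the statistics equal the instance statistics; running
    averages are tracked and used in evaluation mode, which is the behavioral
    difference from :class:`InstanceNorm3d`.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        g = Tensor(np.ones(channels, dtype=_F32))
        g.requires_grad = True
        b = Tensor(np.zeros(channels, dtype=_F32))
        b.requires_grad = True
        self.gamma = g
        self.beta = b
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(1, 2, 3))
            var = x.data.var(axis=(1, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.astype(_F32)
            self.running_var = (1 - m) * self.running_var + m * var.astype(_F32)
            return instance_norm(x, self.gamma, self.beta, eps=self.eps)
        shift = Tensor(self.running_mean[:, None, None, None])
        scale = Tensor(
            (1.0 / np.sqrt(self.running_var + self.eps))[:, None, None, None]
        )
        xhat = (x - shift) * scale
        cshape = (-1, 1, 1, 1)
        return xhat * self.gamma.reshape(*cshape) + self.beta.reshape(*cshape)


_SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))


def _gelu(x: Tensor) -> Tensor:
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * x * x * x)
    return 0.5 * x * (1.0 + inner.tanh())


class Activation(Module):
    """Configurable nonlinearity; ``prelu`` carries a learnable slope."""

    NAMES = ("leaky_relu", "relu", "prelu", "gelu", "silu", "mish")

    def __init__(self, name: str, rng: np.random.Generator | None = None,
                 slope: float = 0.025):
        super().__init__()
        if name not in self.NAMES:
            raise ValueError(f"unknown activation {name!r}; choose from {self.NAMES}")
        self.name = name
        self.slope = slope
        if name == "prelu":
            a = Tensor(np.full((), 0.25, dtype=_F32))
            a.requires_grad = True
            self.alpha = a

    def __call__(self, x: Tensor) -> Tensor:
        if self.name == "leaky_relu":
            return x.leaky_relu(self.slope)
        if self.name == "relu":
            return x.relu()
        if self.name == "prelu":
            return x.relu() - self.alpha * (-x).relu()
        if self.name == "gelu":
            return _gelu(x)
        if self.name == "silu":
            return x * x.sigmoid()
        if self.name == "mish":
            return x * x.softplus().tanh()
        raise AssertionError


def make_norm(kind: str, channels: int) -> Module:
    if kind == "instance":
        return InstanceNorm3d(channels)
    if kind == "batch":
        return BatchNorm3d(channels)
    raise ValueError(f"unknown norm {kind!r}; choose 'instance' or 'batch'")
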