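"""Neural-network building blocks over the numpy autodiff engine.

Layers keep their parameters as :class:`~multiphys._autodiff.Tensor` objects
and are initialized from an explicit ``numpy.random.Generator``, so model
construction is fully determined by a seed. ``Module.train()`` /
``Module.eval()`` toggle batch-norm behaviour exactly as in mainstream deep
learning frameworks: training mode normalizes with batch statistics and
updates running estimates; evaluation mode uses the running estimates (and
therefore works with batch size 1).
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Tensor, concat, conv2d, depthwise_conv1d, selective_scan_diag

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "ModuleList",
    "SelectiveSSM",
    "Adam",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def astype(self, dtype):
        """Cast all parameters in place (float32 for fast training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({"buffer:" + k: b.copy() for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for k, v in d.items():
            if k.startswith("buffer:"):
                buffers[k[len("buffer:"):]][...] = v
            else:
                params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 1):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (B, C, H, W); batch stats in training mode."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self._buffers["running_mean"] = np.zeros(n_ch)
        self._buffers["running_var"] = np.ones(n_ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            if x.shape[0] < 2:
                raise ValueError("BatchNorm2d requires batch size >= 2 in training mode")
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm += self.momentum * (mu.data.reshape(-1) - rm)
            rv += self.momentum * (var.data.reshape(-1) - rv)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
            centered = x - mu
        xh = centered * (var + self.eps).pow(-0.5)
        return xh * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class DepthwiseConv1d(Module):
    """Per-channel 'same' (non-causal) convolution along the token axis."""

    def __init__(self, n_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(kernel)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(n_ch, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv1d(x, self.weight, self.bias)


class SelectiveSSM(Module):
    """Input-dependent diagonal state-space scan over a token sequence.

    Follows the standard selective parameterization: per-token
    ``delta = softplus(Linear(x) + dt_bias)`` (one time-scale per channel),
    per-token ``B_t`` and ``C_t`` from linear projections shared across
    channels, and a shared negative-real diagonal evolution matrix
    ``A[c, i] = -(i + 1)`` stored as ``log(-A)``.

    ``time_invariant=True`` freezes delta/B/C at their sequence means, which
    reduces the layer exactly to a per-channel LTI scan (used for testing
    against :mod:`multiphys.ssm_core`).
    """

    def __init__(self, n_ch: int, state_size: int, rng: np.random.Generator,
                 time_invariant: bool = False):
        super().__init__()
        self.n_ch = n_ch
        self.state_size = state_size
        self.time_invariant = time_invariant
        self.delta_proj = Linear(n_ch, n_ch, rng)
        # softplus(dt_bias) spread over [1e-3, 1e-1]: typical Mamba dt init
        dt = np.exp(rng.uniform(math.log(1e-3), math.log(1e-1), size=n_ch))
        self.dt_bias = Tensor(np.log(np.expm1(dt)), requires_grad=True)
        self.B_proj = Linear(n_ch, state_size, rng)
        self.C_proj = Linear(n_ch, state_size, rng)
        A = np.tile(-(np.arange(1, state_size + 1, dtype=float)), (n_ch, 1))
        self.A_log = Tensor(np.log(-A), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        delta = (self.delta_proj(x) + self.dt_bias).softplus()
        Bt = self.B_proj(x)
        Ct = self.C_proj(x)
        if self.time_invariant:
            delta = delta.mean(axis=1, keepdims=True) * Tensor(np.ones((1, x.shape[1], 1)))
            Bt = Bt.mean(axis=1, keepdims=True) * Tensor(np.ones((1, x.shape[1], 1)))
            Ct = Ct.mean(axis=1, keepdims=True) * Tensor(np.ones((1, x.shape[1], 1)))
        A = -self.A_log.exp()
        return selective_scan_diag(x, delta, Bt, Ct, A)


class Adam:
    """Adam optimizer (Kingma & Ba) over the module's parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# re-exported for layers built directly from ops
Tensor = Tensor
concat = concat
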