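"""Neural-network layers built on the autodiff tensors.

He initialization is used for every convolution: weights are drawn from
N(0, 2/fan_in), the variance that keeps forward activations stable under
rectifier nonlinearities. Biases start at zero.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Sequential", "Conv2d", "BatchNorm2d", "RReLU", "Sigmoid"]


class Module:
    """Base class: parameter registration, train/eval mode, recursion."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for prefix, mod in self._named_modules():
            for name, value in vars(mod).items():
                if isinstance(value, Tensor) and value.requires_grad:
                    yield (f"{prefix}.{name}" if prefix else name), value

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}.{name}" if prefix else name)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        sub = f"{prefix}.{name}.{i}" if prefix else f"{name}.{i}"
                        yield from item._named_modules(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for prefix, mod in self._named_modules():
            if isinstance(mod, BatchNorm2d):
                key = f"{prefix}." if prefix else ""
                state[f"{key}running_mean"] = mod.running_mean.copy()
                state[f"{key}running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=np.float64)
        for prefix, mod in self._named_modules():
            if isinstance(mod, BatchNorm2d):
                key = f"{prefix}." if prefix else ""
                mod.running_mean = np.array(state[f"{key}running_mean"])
                mod.running_var = np.array(state[f"{key}running_var"])


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution with He-initialized weights."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if padding is None:  # "same" padding for stride-1 odd kernels
            padding = dilation * (kernel_size - 1) // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels,
                                       kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval mode."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_channels = num_channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
            count = n * h * w

            def backward(g):
                gamma = self.gamma.data[None, :, None, None]
                if self.gamma.requires_grad:
                    self.gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
                if self.beta.requires_grad:
                    self.beta._accumulate(g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    gxhat = g * gamma
                    s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (inv_std[None, :, None, None] / count) * (
                        count * gxhat - s1 - xhat * s2
                    )
                    x._accumulate(gx)

            out_data = (self.gamma.data[None, :, None, None] * xhat
                        + self.beta.data[None, :, None, None])
            return Tensor._node(out_data, (x, self.gamma, self.beta), backward)

        # eval mode: affine transform with frozen statistics
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * inv_std
        shift = self.beta.data - self.running_mean * scale
        scale_t = scale[None, :, None, None]

        def backward(g):
            if self.gamma.requires_grad:
                xhat = ((x.data - self.running_mean[None, :, None, None])
                        * inv_std[None, :, None, None])
                self.gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if self.beta.requires_grad:
                self.beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accumulate(g * scale_t)

        out_data = x.data * scale_t + shift[None, :, None, None]
        return Tensor._node(out_data, (x, self.gamma, self.beta), backward)


class RReLU(Module):
    """Randomized leaky rectifier.

    The negative-halfline slope is sampled from U(lower, upper) during
    training (a mild stochastic regulariser) and pinned to the midpoint
    (lower+upper)/2 at evaluation time so inference is deterministic.
    """

    def __init__(self, lower: float = 1.0 / 8.0, upper: float = 1.0 / 3.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= lower < upper <= 1.0:
            raise ValueError("RReLU bounds must satisfy 0 <= lower < upper <= 1")
        self.lower = lower
        self.upper = upper
        self.rng = rng if rng is not None else np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        return Tensor._coerce(x).rrelu(self.lower, self.upper, self.training, self.rng)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return Tensor._coerce(x).sigmoid()
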