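"""Neural-network layers on top of the autograd engine.

Includes the trainable Self-ONN (generative-neuron) layer and the two
Self-ONN residual blocks used in the segmentation decoders, alongside the
ordinary convolution/batch-norm/pooling layers the encoder families need.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    avgpool2d,
    concatenate,
    conv2d,
    maxpool2d,
    selfonn2d,
    upsample_bilinear,
)

__all__ = [
    "Parameter", "Module", "Sequential", "Identity", "ReLU", "Tanh",
    "Conv2d", "SelfONN2d", "BatchNorm2d", "MaxPool2d", "AvgPool2d",
    "Upsample", "Softmax2d", "SelfONNConvResBlock", "SelfONNResBlock", "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composable container tracking parameters, submodules and train mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _members(self):
        for name, value in vars(self).items():
            yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in self._members():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, value in self._members():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            src = state[name]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {p.data.shape}")
            p.data = src.copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                if f"__bn{i}.running_mean" in state:
                    m.running_mean = state[f"__bn{i}.running_mean"].copy()
                    m.running_var = state[f"__bn{i}.running_var"].copy()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class SelfONN2d(Module):
    """Trainable generative-neuron layer.

    Each output connection applies q kernels to the elementwise powers
    x, x^2, ..., x^q of its receptive field and sums the responses — a
    truncated MacLaurin series whose coefficients are learned.  With q=1 the
    layer reduces exactly to an ordinary convolution.  Inputs are expected in
    [-1, 1] so that the power terms stay well-conditioned.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 q: int = 3, stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if q < 1:
            raise ValueError(f"Taylor order q must be >= 1, got {q}")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        bound = 1.0 / np.sqrt(fan_in * q)
        self.weight = Parameter(rng.uniform(
            -bound, bound, (q, out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels)) if bias else None
        self.q, self.stride, self.padding = q, stride, padding

    def forward(self, x):
        return selfonn2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.ravel())
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size: int = 2, stride: int = 2):
        super().__init__()
        self.kernel_size, self.stride = kernel_size, stride

    def forward(self, x):
        return avgpool2d(x, self.kernel_size, self.stride)


class Upsample(Module):
    """Bilinear upsampling by an integer scale factor."""

    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        return upsample_bilinear(x, (h * self.scale, w * self.scale))


class Softmax2d(Module):
    """Channel-wise SoftMax for NCHW maps."""

    def forward(self, x):
        shifted = x - Tensor(x.data.max(axis=1, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=1, keepdims=True)


class SelfONNConvResBlock(Module):
    """Two-path Self-ONN block.

    Path A: 3x3 Self-ONN layer (channel expansion) + tanh, then 1x1 Self-ONN
    layer + tanh.  Path B: 3x3 plain convolution on the original input to the
    same channel count.  The two paths are combined at matching spatial size,
    by elementwise addition by default or channel concatenation when
    ``combine='concat'``.
    """

    def __init__(self, in_channels: int, out_channels: int, q: int = 3,
                 combine: str = "add", rng: np.random.Generator | None = None):
        super().__init__()
        if combine not in ("add", "concat"):
            raise ValueError(f"combine must be 'add' or 'concat', got {combine!r}")
        rng = rng or np.random.default_rng(0)
        self.onn3 = SelfONN2d(in_channels, out_channels, 3, q=q, padding=1, rng=rng)
        self.onn1 = SelfONN2d(out_channels, out_channels, 1, q=q, rng=rng)
        self.conv = Conv2d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.act = Tanh()
        self.combine = combine

    def forward(self, x):
        a = self.act(self.onn1(self.act(self.onn3(x))))
        b = self.conv(x)
        if a.shape[1] != b.shape[1]:
            raise ValueError(f"path channel mismatch: {a.shape[1]} vs {b.shape[1]}")
        if self.combine == "add":
            return a + b
        return concatenate([a, b], axis=1)

    def selfonn_path(self, x):
        """Self-ONN path alone (tanh-activated, so entries lie in (-1, 1))."""
        return self.act(self.onn1(self.act(self.onn3(x))))


class SelfONNResBlock(Module):
    """Residual Self-ONN block: 3x3 Self-ONN (channel reduction) + tanh,
    1x1 Self-ONN restoring the input channel count + tanh, then residual
    addition with the input.  Spatial size is preserved throughout."""

    def __init__(self, channels: int, reduction: int = 4, q: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        mid = max(channels // reduction, 1)
        self.onn3 = SelfONN2d(channels, mid, 3, q=q, padding=1, rng=rng)
        self.onn1 = SelfONN2d(mid, channels, 1, q=q, rng=rng)
        self.act = Tanh()

    def forward(self, x):
        y = self.act(self.onn1(self.act(self.onn3(x))))
        if y.shape != x.shape:
            raise ValueError(f"residual shape mismatch: {y.shape} vs {x.shape}")
        return y + x


class Adam:
    """Adam optimizer (betas 0.9/0.999 as used for the segmentation models)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
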