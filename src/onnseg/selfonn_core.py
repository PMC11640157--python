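"""The generative-neuron (Self-ONN) operator.

A generative neuron replaces the fixed linear kernel of a convolutional
neuron with a learned truncated MacLaurin series: the response of a
connection to input value x is

    f(x) = c + v1 x + v2 x^2 + ... + vq x^q,

where the coefficients v1..vq are per-connection kernels learned by
backpropagation and c is a per-output-channel bias.  The pool operator is
summation, so the layer output is

    out[o, y, x] = bias[o] + sum_k sum_{i,u,v} w[k-1, o, i, u, v] * x_in[i, ...]^k

with zero padding outside the input support.  With q = 1 this reduces
exactly to ordinary cross-correlation.

This module provides the functional form on plain NumPy arrays (channels x
height x width feature maps) plus an intentionally naive nested-loop
reference implementation used as an independent oracle in tests.  The
trainable layer/block classes live in :mod:`onnseg.nn`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor

__all__ = [
    "SelfONNLayerSpec",
    "TaylorCoefficients",
    "selfonn_forward",
    "selfonn_forward_bruteforce",
    "selfonn_conv_resblock",
    "selfonn_resblock",
    "random_coefficients",
]


@dataclass(frozen=True)
class SelfONNLayerSpec:
    """Shape/order description of one generative-neuron layer."""

    in_channels: int
    out_channels: int
    kernel_size: int
    q: int = 3
    stride: int = 1
    padding: int = 0
    has_bias: bool = True

    def __post_init__(self):
        if self.q < 1:
            raise ValueError(f"Taylor order q must be >= 1, got {self.q}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be a positive odd integer, got {self.kernel_size}")
        if self.stride < 1:
            raise ValueError("stride must be positive")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")

    @property
    def parameter_count(self) -> int:
        """q * in * out * k^2 weights plus one bias per output channel."""
        n = self.q * self.in_channels * self.out_channels * self.kernel_size ** 2
        return n + (self.out_channels if self.has_bias else 0)

    @property
    def weight_shape(self) -> tuple[int, int, int, int, int]:
        k = self.kernel_size
        return (self.q, self.out_channels, self.in_channels, k, k)


@dataclass
class TaylorCoefficients:
    """The learned series coefficients v1..vq (one kernel per power) and bias c."""

    weights: np.ndarray  # (q, out, in, k, k)
    bias: np.ndarray | None  # (out,) or None

    def validate(self, spec: SelfONNLayerSpec) -> None:
        if self.weights.shape != spec.weight_shape:
            raise ValueError(
                f"weights shape {self.weights.shape} does not match spec {spec.weight_shape}")
        if spec.has_bias:
            if self.bias is None or self.bias.shape != (spec.out_channels,):
                raise ValueError("bias missing or mis-shaped for spec with has_bias=True")
        elif self.bias is not None:
            raise ValueError("bias provided for spec with has_bias=False")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")
        if self.bias is not None and not np.all(np.isfinite(self.bias)):
            raise ValueError("non-finite bias")


def random_coefficients(spec: SelfONNLayerSpec, rng: np.random.Generator) -> TaylorCoefficients:
    """Variance-scaled uniform init: U(-1/sqrt(fan_in*q), 1/sqrt(fan_in*q)) per power."""
    fan_in = spec.in_channels * spec.kernel_size ** 2
    bound = 1.0 / np.sqrt(fan_in * spec.q)
    weights = rng.uniform(-bound, bound, spec.weight_shape)
    bias = rng.uniform(-bound, bound, spec.out_channels) if spec.has_bias else None
    return TaylorCoefficients(weights, bias)


def _check_input(x: np.ndarray, spec: SelfONNLayerSpec) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected (channels, height, width) input, got shape {x.shape}")
    if x.shape[0] != spec.in_channels:
        raise ValueError(f"input has {x.shape[0]} channels, spec expects {spec.in_channels}")
    return x


def selfonn_forward(x: np.ndarray, spec: SelfONNLayerSpec, coef: TaylorCoefficients) -> np.ndarray:
    """Vectorized generative-neuron forward pass on one feature map."""
    x = _check_input(x, spec)
    coef.validate(spec)
    from .autograd import selfonn2d

    xt = Tensor(x[None])
    wt = Tensor(coef.weights)
    bt = Tensor(coef.bias) if coef.bias is not None else None
    out = selfonn2d(xt, wt, bt, stride=spec.stride, padding=spec.padding)
    return out.data[0]


def selfonn_forward_bruteforce(x: np.ndarray, spec: SelfONNLayerSpec,
                               coef: TaylorCoefficients) -> np.ndarray:
    """Nested-loop reference implementation (the independent oracle).

    Loops explicitly over output pixels, output channels, input channels,
    kernel offsets and powers; out-of-bounds input positions contribute zero.
    """
    x = _check_input(x, spec)
    coef.validate(spec)
    cin, h, w = x.shape
    k, s, p = spec.kernel_size, spec.stride, spec.padding
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("kernel larger than padded input")
    out = np.zeros((spec.out_channels, ho, wo))
    for o in range(spec.out_channels):
        for yy in range(ho):
            for xx in range(wo):
                acc = 0.0 if coef.bias is None else float(coef.bias[o])
                for i in range(cin):
                    for u in range(k):
                        for v in range(k):
                            yi = yy * s + u - p
                            xi = xx * s + v - p
                            if not (0 <= yi < h and 0 <= xi < w):
                                continue
                            val = x[i, yi, xi]
                            for power in range(1, spec.q + 1):
                                acc += coef.weights[power - 1, o, i, u, v] * val ** power
                out[o, yy, xx] = acc
    return out


def selfonn_conv_resblock(x: np.ndarray, block: "nn.SelfONNConvResBlock") -> np.ndarray:
    """Apply a two-path Self-ONN Conv ResBlock to a (C, H, W) feature map."""
    out = block(Tensor(np.asarray(x, dtype=np.float64)[None]))
    return out.data[0]


def selfonn_resblock(x: np.ndarray, block: "nn.SelfONNResBlock") -> np.ndarray:
    """Apply a residual Self-ONN block to a (C, H, W) feature map."""
    out = block(Tensor(np.asarray(x, dtype=np.float64)[None]))
    return out.data[0]
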