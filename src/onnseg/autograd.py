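"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine records a dynamic graph of :class:`Tensor` operations and computes
vector-Jacobian products on :meth:`Tensor.backward`.  Only the operations the
segmentation stack needs are provided: broadcast arithmetic, integer powers,
tanh/relu/exp, reductions, matmul, concatenation, 2-D cross-correlation
(plain and Self-ONN), pooling and bilinear upsampling.  All convolution-style
operations share one im2col/col2im pair so their gradients are exercised by
the same finite-difference checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "conv2d",
    "selfonn2d",
    "maxpool2d",
    "avgpool2d",
    "upsample_bilinear",
    "numerical_gradient",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.data.shape), _unbroadcast(gb, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise non-linearities -------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    # -- reductions & shaping ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src = self.data.shape
        return Tensor._from_op(out_data, (self,), lambda g: (g.reshape(src),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)
        return Tensor._from_op(out_data, (self,), lambda g: (g.transpose(inv),))

    # -- backprop ---------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


# ---------------------------------------------------------------------------
# im2col / col2im shared by the convolution-style operations
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, c, hp, wp = x.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"kernel {kh}x{kw} larger than padded input {hp}x{wp}")
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, padding: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    d = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    gx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for u in range(kh):
        for v in range(kw):
            gx[:, :, u : u + ho * stride : stride, v : v + wo * stride : stride] += d[:, :, u, v]
    return gx[:, :, padding : padding + h, padding : padding + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    o, c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {c}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(o, -1)
    out = cols @ wmat.T  # (n, L, o)
    if bias is not None:
        out = out + bias.data
    n = x.shape[0]
    out_data = out.transpose(0, 2, 1).reshape(n, o, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(n, o, ho * wo).transpose(0, 2, 1)  # (n, L, o)
        gw = np.einsum("nlo,nlc->oc", gmat, cols).reshape(weight.shape)
        gx = _col2im(gmat @ wmat, x.shape, kh, kw, stride, padding)
        if bias is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out_data, parents, backward)


def selfonn2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Generative-neuron cross-correlation.

    `weight` has shape (q, O, C, kh, kw); power term p applies kernel
    weight[p-1] to the elementwise p-th power of the input window, and the
    per-power responses are summed (MacLaurin-series nodal operator with
    summation pooling).
    """
    q, o, c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"selfonn2d: input has {x.shape[1]} channels, weight expects {c}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    n = x.shape[0]
    wmats = weight.data.reshape(q, o, -1)
    powcols = [cols]
    for _ in range(1, q):
        powcols.append(powcols[-1] * cols)
    out = powcols[0] @ wmats[0].T
    for p in range(1, q):
        out += powcols[p] @ wmats[p].T
    if bias is not None:
        out = out + bias.data
    out_data = out.transpose(0, 2, 1).reshape(n, o, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(n, o, ho * wo).transpose(0, 2, 1)
        gw = np.empty_like(weight.data)
        dcols = np.zeros_like(cols)
        for p in range(q):
            gw[p] = np.einsum("nlo,nlc->oc", gmat, powcols[p]).reshape(o, c, kh, kw)
            dpow = gmat @ wmats[p]
            if p == 0:
                dcols += dpow
            else:
                dcols += dpow * (p + 1) * powcols[p - 1]
        gx = _col2im(dcols, x.shape, kh, kw, stride, padding)
        if bias is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out_data, parents, backward)


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    hp, wp = xp.shape[2:]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride].reshape(n, c, ho, wo, kernel * kernel)
    arg = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gx = np.zeros((n, c, hp, wp), dtype=g.dtype)
        u = arg // kernel
        v = arg % kernel
        ni, ci, hi, wi = np.ogrid[:n, :c, :ho, :wo]
        rows = hi * stride + u
        colsi = wi * stride + v
        np.add.at(gx, (np.broadcast_to(ni, arg.shape), np.broadcast_to(ci, arg.shape), rows, colsi), g)
        if padding:
            gx = gx[:, :, padding : padding + h, padding : padding + w]
        return (gx,)

    return Tensor._from_op(out_data, (x,), backward)


def avgpool2d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    n, c, h, w = x.shape
    ho, wo = (h - kernel) // stride + 1, (w - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kernel, kernel), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]
    out_data = windows.mean(axis=(-1, -2))
    inv = 1.0 / (kernel * kernel)

    def backward(g):
        gx = np.zeros((n, c, h, w), dtype=g.dtype)
        for u in range(kernel):
            for v in range(kernel):
                gx[:, :, u : u + ho * stride : stride, v : v + wo * stride : stride] += g * inv
        return (gx,)

    return Tensor._from_op(out_data, (x,), backward)


def _bilinear_indices(n_in: int, n_out: int):
    # half-pixel-centre convention (matches the common DL upsampling default)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    return i0, i1, frac


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    n, c, h, w = x.shape
    ho, wo = size
    r0, r1, rf = _bilinear_indices(h, ho)
    c0, c1, cf = _bilinear_indices(w, wo)
    rf = rf[:, None]
    cf = cf[None, :]
    d = x.data
    out_data = (
        d[:, :, r0[:, None], c0[None, :]] * (1 - rf) * (1 - cf)
        + d[:, :, r0[:, None], c1[None, :]] * (1 - rf) * cf
        + d[:, :, r1[:, None], c0[None, :]] * rf * (1 - cf)
        + d[:, :, r1[:, None], c1[None, :]] * rf * cf
    )

    def backward(g):
        gx = np.zeros((n, c, h, w), dtype=g.dtype)
        ri = np.broadcast_to(np.arange(n)[:, None, None, None], g.shape)
        ci_ = np.broadcast_to(np.arange(c)[None, :, None, None], g.shape)
        for rr, cc, ww in (
            (r0[:, None], c0[None, :], (1 - rf) * (1 - cf)),
            (r0[:, None], c1[None, :], (1 - rf) * cf),
            (r1[:, None], c0[None, :], rf * (1 - cf)),
            (r1[:, None], c1[None, :], rf * cf),
        ):
            np.add.at(
                gx,
                (ri, ci_, np.broadcast_to(rr, g.shape[2:]), np.broadcast_to(cc, g.shape[2:])),
                g * ww,
            )
        return (gx,)

    return Tensor._from_op(out_data, (x,), backward)


def concatenate(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def numerical_gradient(f, arr: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar f with respect to arr."""
    grad = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
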