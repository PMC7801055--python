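"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the segmentation network and its losses
need: convolution (stride/dilation/padding), batch normalisation, randomized
leaky rectifiers, bilinear upsampling, channel concatenation/slicing, global
average pooling, and elementwise arithmetic with broadcasting.  Gradients are
accumulated by topological-order backpropagation over a dynamically recorded
tape, micrograd-style, but with ndarray-valued nodes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["Tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # defer all numpy operator dispatch to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph plumbing -------------------------------------------------------
    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._node(out_data, (self, other), backward)

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._node(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor._node(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        # clip the logit so exp never overflows, and keep the output strictly
        # inside (0, 1) even when float64 would round the saturated value
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        s = np.clip(s, 1e-12, 1.0 - 1e-12)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._node(s, (self,), backward)

    def clamp(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._node(np.clip(self.data, lo, hi), (self,), backward)

    def clamp_passthrough(self, lo: float, hi: float):
        """Clip values but propagate gradients unchanged (straight-through).

        Used for probability clamping inside losses: a prediction saturated
        past the clamp must still receive a corrective gradient, otherwise
        confidently wrong pixels go permanently silent.
        """

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)

        return Tensor._node(np.clip(self.data, lo, hi), (self,), backward)

    def rrelu(self, lower: float, upper: float, training: bool, rng=None):
        """Randomized leaky ReLU.

        In training mode the negative slope is drawn i.i.d. per element from
        U(lower, upper); in evaluation mode it is fixed at the interval
        midpoint, making the forward pass deterministic.
        """
        if training:
            if rng is None:
                raise ValueError("training-mode RReLU requires an rng")
            slopes = rng.uniform(lower, upper, size=self.data.shape)
        else:
            slopes = (lower + upper) / 2.0
        factor = np.where(self.data >= 0, 1.0, slopes)
        out_data = self.data * factor

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor._node(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._node(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g / n, self.data.shape).copy())

        return Tensor._node(self.data.mean(), (self,), backward)

    def mean_spatial(self):
        """Global average pool: mean over the trailing (H, W) axes, keepdims."""
        h, w = self.data.shape[-2:]
        out_data = self.data.mean(axis=(-2, -1), keepdims=True)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g / (h * w), self.data.shape).copy())

        return Tensor._node(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def narrow_channels(self, start: int, stop: int):
        """Slice channels [start, stop) of an (N, C, H, W) tensor."""
        out_data = self.data[:, start:stop]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accumulate(full)

        return Tensor._node(out_data, (self,), backward)

    def upsample_bilinear_2x(self):
        """Double H and W by bilinear interpolation (half-pixel-centre grid)."""
        n, c, h, w = self.data.shape
        ah = _bilinear_matrix(h)
        aw = _bilinear_matrix(w)
        out_data = ah @ self.data @ aw.T

        def backward(g):
            if self.requires_grad:
                self._accumulate(ah.T @ g @ aw)

        return Tensor._node(out_data, (self,), backward)


@lru_cache(maxsize=64)
def _bilinear_matrix(n: int) -> np.ndarray:
    """(2n, n) interpolation matrix doubling a length-n axis bilinearly."""
    a = np.zeros((2 * n, n))
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        a[i, lo_c] += 1.0 - frac
        a[i, hi_c] += frac
    return a


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along the channel axis."""
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    edges = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, edges[:-1], edges[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._node(out_data, tuple(tensors), backward)


# -- convolution --------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*kh*kw, oh*ow) patch matrix."""
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            r0 = i * dilation
            c0 = j * dilation
            cols[:, :, i, j] = xp[:, :, r0:r0 + stride * oh:stride,
                                  c0:c0 + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(gcols: np.ndarray, xp_shape: tuple, kh: int, kw: int, stride: int,
            dilation: int, oh: int, ow: int) -> np.ndarray:
    """Scatter-add inverse of _im2col."""
    n, c, hp, wp = xp_shape
    gx = np.zeros(xp_shape, dtype=gcols.dtype)
    g6 = gcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            r0 = i * dilation
            c0 = j * dilation
            gx[:, :, r0:r0 + stride * oh:stride,
               c0:c0 + stride * ow:stride] += g6[:, :, i, j]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation of an (N, C, H, W) tensor with (O, C, kh, kw) weights."""
    x = Tensor._coerce(x)
    n, c, h, w = x.data.shape
    oc, ic, kh, kw = weight.data.shape
    if ic != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ic}")
    kh_eff = dilation * (kh - 1) + 1
    kw_eff = dilation * (kw - 1) + 1
    oh = (h + 2 * padding - kh_eff) // stride + 1
    ow = (w + 2 * padding - kw_eff) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError("conv2d: kernel larger than padded input")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)
    wmat = weight.data.reshape(oc, ic * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(n, oc, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, oc, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gflat = g.reshape(n, oc, oh * ow)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.matmul(gflat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gflat)
            gxp = _col2im(gcols, xp.shape, kh, kw, stride, dilation, oh, ow)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._node(out_data, parents, backward)
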