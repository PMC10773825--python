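"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation networks in this package are expressed as graphs of
:class:`Tensor` operations.  Each operation records its parents and a
closure that propagates the upstream gradient; :meth:`Tensor.backward`
runs the closures in reverse topological order.  Only the operations the
networks need are provided — this is not a general deep-learning
framework.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, special


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32) if not isinstance(data, np.ndarray) else data
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        grad = np.asarray(grad, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep at full resolution
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free intermediate gradients to bound memory
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))))

    def __rsub__(self, other):
        return Tensor(np.asarray(other, self.dtype)) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, self.dtype)) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bw(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), bw)

    def __matmul__(self, other):
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(a.data, axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bw)

    def pad(self, pad_width):
        a = self
        slices = tuple(slice(lo, lo + n) for (lo, _), n in zip(pad_width, a.shape))

        def bw(g):
            a._accum(g[slices])

        return Tensor._make(np.pad(a.data, pad_width), (a,), bw)

    def roll(self, shift, axis):
        a = self

        def bw(g):
            a._accum(np.roll(g, tuple(-s for s in shift), axis))

        return Tensor._make(np.roll(a.data, shift, axis), (a,), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape))

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        a = self
        out_data = special.expit(a.data)

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def leaky_relu(self, slope: float = 0.01):
        a = self
        factor = np.where(a.data > 0, 1.0, slope).astype(a.dtype)

        def bw(g):
            a._accum(g * factor)

        return Tensor._make(a.data * factor, (a,), bw)

    def gelu(self):
        """Gaussian error linear unit, exact (erf) form."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + special.erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bw(g):
            a._accum(g * (cdf + x * pdf))

        return Tensor._make(x * cdf, (a,), bw)

    def softmax(self, axis: int = -1):
        shifted = self + Tensor(-self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    parts = list(tensors)
    sizes = [t.shape[axis] for t in parts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in parts], axis=axis), parts, bw)


# -- spatial operators --------------------------------------------------------

def _box_sum(x: np.ndarray, kernel: int) -> np.ndarray:
    """Zero-padded K^3 neighborhood sum over the last three axes."""
    out = ndimage.uniform_filter1d(x, kernel, axis=-3, mode="constant", origin=0)
    out = ndimage.uniform_filter1d(out, kernel, axis=-2, mode="constant", origin=0)
    out = ndimage.uniform_filter1d(out, kernel, axis=-1, mode="constant", origin=0)
    return out * float(kernel) ** 3


def _neighbor_counts(shape3, kernel: int) -> np.ndarray:
    ones = np.ones(shape3, dtype=np.float64)
    return np.rint(_box_sum(ones, kernel))


def avg_pool3d_same(x: Tensor, kernel: int) -> Tensor:
    """Stride-1 average pooling over a centered K^3 neighborhood.

    Border voxels average only their in-bounds neighbors (padded positions
    are excluded from both numerator and denominator), so a constant field
    is mapped to itself everywhere.  The operator has no parameters.
    """
    if kernel % 2 != 1 or kernel < 1:
        raise ValueError(f"pooling kernel must be a positive odd integer, got {kernel}")
    a = x
    counts = _neighbor_counts(a.shape[-3:], kernel)
    out_data = (_box_sum(a.data.astype(np.float64), kernel) / counts).astype(a.dtype)

    def bw(g):
        gx = _box_sum(g.astype(np.float64) / counts, kernel)
        a._accum(gx.astype(a.dtype))

    return Tensor._make(out_data, (a,), bw)


def _im2col(x: np.ndarray, kernel: int, stride: int, padding: int):
    n, c, d, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
    view = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel, kernel), axis=(2, 3, 4))
    view = view[:, :, ::stride, ::stride, ::stride]  # (N,C,Do,Ho,Wo,k,k,k)
    do, ho, wo = view.shape[2:5]
    cols = view.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * kernel ** 3)
    return np.ascontiguousarray(cols), (do, ho, wo)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """3D convolution; ``weight`` has shape (out, in, k, k, k)."""
    o, ci, k, _, _ = weight.shape
    n = x.shape[0]
    cols, (do, ho, wo) = _im2col(x.data, k, stride, padding)
    wmat = weight.data.reshape(o, ci * k ** 3)
    out = cols @ wmat.T  # (N*Do*Ho*Wo, O)
    del cols
    if bias is not None:
        out = out + bias.data
    out = out.reshape(n, do, ho, wo, o).transpose(0, 4, 1, 2, 3)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(-1, o)
        if weight.requires_grad:
            # columns are recomputed here rather than kept alive from the
            # forward pass: peak memory then holds one column matrix at a
            # time instead of one per convolution in the graph
            cols_b, _ = _im2col(x.data, k, stride, padding)
            weight._accum((gmat.T @ cols_b).reshape(weight.shape))
            del cols_b
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            if stride == 1:
                # dx is the full correlation of g with the flipped kernel
                wflip = weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                gview = g.reshape(n, o, do, ho, wo)
                gcols2, _ = _im2col(gview, k, 1, k - 1 - padding)
                gx = gcols2 @ wflip.reshape(ci, o * k ** 3).T
                x._accum(gx.reshape(n, *x.shape[2:], ci).transpose(0, 4, 1, 2, 3))
            else:
                gcols = gmat @ wmat  # (N*out_vox, C*k^3)
                xp_shape = (n, ci) + tuple(s + 2 * padding for s in x.shape[2:])
                gx = np.zeros(xp_shape, dtype=x.dtype)
                gcols = gcols.reshape(n, do, ho, wo, ci, k, k, k)
                for kd in range(k):
                    for kh in range(k):
                        for kw in range(k):
                            gx[:, :, kd:kd + do * stride:stride,
                               kh:kh + ho * stride:stride,
                               kw:kw + wo * stride:stride] += \
                                gcols[:, :, :, :, :, kd, kh, kw].transpose(0, 4, 1, 2, 3)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding, padding:-padding]
                x._accum(gx)

    return Tensor._make(np.ascontiguousarray(out), parents, bw)


def conv_transpose3d_up2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

    ``weight`` has shape (in, out, 2, 2, 2).  With stride equal to the
    kernel the output blocks do not overlap, so the operator is a linear
    map from each input voxel to a 2x2x2 output block.
    """
    n, ci, d, h, w = x.shape
    _, o, _, _, _ = weight.shape
    wmat = weight.data.reshape(ci, o * 8)
    out = np.tensordot(x.data, wmat, axes=([1], [0]))  # (N,D,H,W,O*8)
    out = out.reshape(n, d, h, w, o, 2, 2, 2).transpose(0, 4, 1, 5, 2, 6, 3, 7)
    out = out.reshape(n, o, 2 * d, 2 * h, 2 * w)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gblk = g.reshape(n, o, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        gblk = gblk.reshape(n, d, h, w, o * 8)
        if x.requires_grad:
            x._accum(np.tensordot(gblk, wmat, axes=([4], [1])).transpose(0, 4, 1, 2, 3))
        if weight.requires_grad:
            gw = np.tensordot(x.data, gblk, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(np.ascontiguousarray(out), parents, bw)


def layer_norm(x: Tensor, weight: Tensor | None, bias: Tensor | None,
               axis: int = -1, eps: float = 1e-5) -> Tensor:
    """Layer normalization over ``axis`` with optional affine parameters."""
    mu = x.mean(axis=axis, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axis, keepdims=True)
    xn = xc * (var + eps) ** -0.5
    if weight is not None:
        shape = [1] * x.ndim
        shape[axis] = x.shape[axis]
        xn = xn * weight.reshape(shape) + bias.reshape(shape)
    return xn


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel spatial normalization without affine terms."""
    axes = tuple(range(2, x.ndim))
    mu = x.mean(axis=axes, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    return xc * (var + eps) ** -0.5
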