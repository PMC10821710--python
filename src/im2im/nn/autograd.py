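"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Everything trainable in this package (U-Nets, discriminators, the spatial-embedding
loss) is expressed through :class:`Tensor`. The op set is deliberately minimal:
elementwise arithmetic, reductions, N-dimensional strided convolution,
nearest-neighbour upsampling, concatenation, slicing and padding — exactly what the
built-in backbones and losses need. Gradients are accumulated into ``Tensor.grad``
as float32 arrays by :meth:`Tensor.backward`.

All arithmetic is float32 throughout, which makes training runs bitwise
reproducible on a single CPU for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor", "concatenate", "gradcheck"]

_F32 = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the graph edges needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic ------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, _F32(1.0), _F32(slope))
        return Tensor._make(self.data * factor, (self,), lambda g: (g * factor,))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only where unclipped."""
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g, dtype=_F32)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).astype(_F32),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * _F32(1.0 / n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros(self.shape, dtype=_F32)
            full[idx] = g
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    def pad(self, pad_width):
        """Zero padding; pad_width as for np.pad."""
        out_data = np.pad(self.data, pad_width)
        sl = tuple(
            slice(p[0], p[0] + s) for p, s in zip(pad_width, self.shape)
        )
        return Tensor._make(out_data, (self,), lambda g: (g[sl],))

    def upsample_nearest(self, factors):
        """Repeat each voxel ``factors[a]`` times along trailing spatial axes.

        ``factors`` has one entry per spatial axis; the first two axes (N, C)
        are untouched.
        """
        factors = tuple(int(f) for f in factors)
        out_data = self.data
        for a, f in enumerate(factors):
            if f > 1:
                out_data = np.repeat(out_data, f, axis=2 + a)

        in_spatial = self.shape[2:]

        def backward(g):
            # inverse of repeat is block-sum
            for a, f in reversed(list(enumerate(factors))):
                if f > 1:
                    shp = list(g.shape)
                    shp[2 + a : 3 + a] = [in_spatial[a], f]
                    g = g.reshape(shp).sum(axis=3 + a)
            return (g.astype(_F32),)

        return Tensor._make(out_data, (self,), backward)

    # -- convolution -------------------------------------------------------
    def conv(self, weight: "Tensor", bias: "Tensor | None", stride, padding):
        """N-d cross-correlation.

        self: (N, Cin, *S); weight: (Cout, Cin, *K); stride/padding per spatial
        axis. Zero padding. Output spatial extent: (S + 2p - K)//s + 1.
        """
        x, w = self.data, weight.data
        d = x.ndim - 2
        stride = tuple(int(s) for s in stride)
        padding = tuple(int(p) for p in padding)
        ksz = w.shape[2:]

        pw = [(0, 0), (0, 0)] + [(p, p) for p in padding]
        xp = np.pad(x, pw)
        win = sliding_window_view(xp, ksz, axis=tuple(range(2, 2 + d)))
        win = win[(slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)]
        # win: (N, Cin, *O, *K); contract Cin and K against weight
        axes_win = [1] + list(range(2 + d, 2 + 2 * d))
        axes_w = [1] + list(range(2, 2 + d))
        out_data = np.tensordot(win, w, axes=(axes_win, axes_w))  # (N, *O, Cout)
        out_data = np.moveaxis(out_data, -1, 1).astype(_F32, copy=False)
        out_data = np.ascontiguousarray(out_data)
        if bias is not None:
            out_data = out_data + bias.data.reshape((1, -1) + (1,) * d)

        ospatial = out_data.shape[2:]
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            # d/dw: contract g with the input windows over (N, *O)
            axes_g = [0] + list(range(2, 2 + d))
            gw = np.tensordot(g, win, axes=(axes_g, axes_g))  # (Cout, Cin, *K)
            # d/dx: scatter weight * g back onto the padded input
            gxp = np.zeros(xp.shape, dtype=_F32)
            for j in np.ndindex(*ksz):
                wj = w[(slice(None), slice(None)) + j]  # (Cout, Cin)
                contrib = np.tensordot(g, wj, axes=([1], [0]))  # (N, *O, Cin)
                contrib = np.moveaxis(contrib, -1, 1)
                sl = tuple(
                    slice(j[a], j[a] + stride[a] * ospatial[a], stride[a])
                    for a in range(d)
                )
                gxp[(slice(None), slice(None)) + sl] += contrib
            unpad = tuple(
                slice(p, p + s) for p, s in zip(padding, x.shape[2:])
            )
            gx = gxp[(slice(None), slice(None)) + unpad]
            if bias is None:
                return gx, gw.astype(_F32)
            gb = g.sum(axis=(0,) + tuple(range(2, 2 + d)))
            return gx, gw.astype(_F32), gb.astype(_F32)

        return Tensor._make(out_data, parents, backward)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=_F32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node.grad += g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if p._backward is None:  # leaf
                    if p.grad is None:
                        p.grad = np.zeros_like(p.data)
                    p.grad += pg
                else:
                    key = id(p)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = np.asarray(pg, dtype=_F32)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for i in range(len(sizes)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor._make(out_data, tuple(tensors), backward)


def gradcheck(fn, inputs: list[Tensor], eps: float = 1e-3, atol: float = 1e-2) -> bool:
    """Compare analytic gradients of scalar ``fn(*inputs)`` to central differences.

    float32 arithmetic limits attainable precision; tolerances are set accordingly.
    Used by the test suite to certify the op set.
    """
    for t in inputs:
        t.grad = None
    out = fn(*inputs)
    out.backward()
    ok = True
    for t in inputs:
        if not t.requires_grad:
            continue
        num = np.zeros_like(t.data, dtype=np.float64)
        flat = t.data.reshape(-1)
        nflat = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn(*inputs).data)
            flat[i] = orig - eps
            lo = float(fn(*inputs).data)
            flat[i] = orig
            nflat[i] = (hi - lo) / (2 * eps)
        if not np.allclose(t.grad, num, atol=atol, rtol=5e-2):
            ok = False
    return ok
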