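"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the bottleneck model needs: broadcasted
arithmetic, matrix multiplication, SiLU / sigmoid / softplus nonlinearities,
a stride-1 'same' 2-D convolution, non-overlapping max-pooling, reshaping
and reductions. Everything runs in float64; gradients are accumulated by a
topological-order backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d_same", "maxpool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes that were broadcast from size 1.
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = tuple(parents)

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------------
    # nonlinearities
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.abs(self.data))),
                     np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = Tensor(s, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def silu(self) -> "Tensor":
        """SiLU(x) = x * sigmoid(x); derivative s(x)(1 + x(1 - s(x)))."""
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(self.data * s, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 + self.data * (1.0 - s)))

        out._backward = backward
        return out

    def softplus(self) -> "Tensor":
        """Numerically stable log(1 + exp(x)); derivative sigmoid(x)."""
        val = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor(val, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
                self._accum(g * s)

        out._backward = backward
        return out

    # ------------------------------------------------------------------
    # shape and reductions
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


# ----------------------------------------------------------------------
# structured ops


def conv2d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1 2-D convolution with size-preserving zero padding.

    x: (N, C_in, H, W); weight: (C_out, C_in, k, k); bias: (C_out,).
    """
    n, c_in, h, w = x.shape
    c_out, c_in_w, k, k2 = weight.shape
    if c_in_w != c_in or k != k2:
        raise ValueError("convolution weight shape mismatch")
    p0, p1 = k // 2, (k - 1) // 2  # asymmetric for even kernels
    xp = np.pad(x.data, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
    out_data = np.zeros((n, c_out, h, w))
    for di in range(k):
        for dj in range(k):
            patch = xp[:, :, di:di + h, dj:dj + w]
            out_data += np.einsum("nchw,fc->nfhw", patch, weight.data[:, :, di, dj])
    out_data += bias.data[None, :, None, None]

    requires = x.requires_grad or weight.requires_grad or bias.requires_grad
    out = Tensor(out_data, requires, (x, weight, bias))

    def backward(g):
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            for di in range(k):
                for dj in range(k):
                    patch = xp[:, :, di:di + h, dj:dj + w]
                    gw[:, :, di, dj] = np.einsum("nfhw,nchw->fc", g, patch)
            weight._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    gxp[:, :, di:di + h, dj:dj + w] += np.einsum(
                        "nfhw,fc->nchw", g, weight.data[:, :, di, dj])
            x._accum(gxp[:, :, p0:p0 + h, p0:p0 + w])

    out._backward = backward
    return out


def maxpool2d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling; trailing rows/cols beyond a multiple of
    `pool` are dropped (floor semantics)."""
    n, c, h, w = x.shape
    h2, w2 = h // pool, w // pool
    if h2 == 0 or w2 == 0:
        raise ValueError("pooling window larger than input")
    cropped = x.data[:, :, :h2 * pool, :w2 * pool]
    windows = cropped.reshape(n, c, h2, pool, w2, pool)
    windows = windows.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, pool * pool)
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    def backward(g):
        if not x.requires_grad:
            return
        gw = np.zeros((n, c, h2, w2, pool * pool))
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(n, c, h2, w2, pool, pool).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, :h2 * pool, :w2 * pool] = gw.reshape(n, c, h2 * pool, w2 * pool)
        x._accum(gx)

    out._backward = backward
    return out
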