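"""Compact reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the saliency models need — elementwise
arithmetic, matrix products (including stacked/batched matmul for
multi-head attention), ReLU, softmax, layer normalization, 2-D convolution
via im2col, 2x2 max pooling, nearest-neighbour 2x upsampling, reshapes and
reductions.  Gradients are accumulated by topological-order backpropagation
from a scalar loss.

The engine is deliberately small and single-sample (no batch axis inside a
Tensor); training loops average gradients over a mini-batch by repeated
forward/backward passes, which is the natural regime at the desk scales
this package trains at.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # ---- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- helpers --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out.requires_grad = self._needs(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out.requires_grad = self._needs(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out.requires_grad = self._needs(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bw
        return out

    def __matmul__(self, other):
        """Matrix product; supports stacked operands with matching batch dims."""
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        out.requires_grad = self._needs(other)
        a, b = self.data, other.data

        def bw(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    def square(self):
        return self * self

    # ---- nonlinearities --------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accum(g * mask)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))
        out.requires_grad = self.requires_grad

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))

        out._backward = bw
        return out

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis to zero mean, unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = Tensor(y, parents=(self,))
        out.requires_grad = self.requires_grad
        n = self.data.shape[-1]

        def bw(g):
            gy = g
            dx = (
                gy - gy.mean(axis=-1, keepdims=True) - y * (gy * y).mean(axis=-1, keepdims=True)
            ) * inv
            self._accum(dx)

        out._backward = bw
        return out

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    # ---- reductions ------------------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape).copy())
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / n, self.data.shape).copy()
        )
        return out

    # ---- spatial ops (C, H, W layout) -----------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", padding: int):
        """2-D convolution of a (Cin, H, W) input with (Cout, Cin, kh, kw) weights.

        Implemented as im2col followed by a single matrix product; stride 1.
        """
        x = self.data
        w, b = weight.data, bias.data
        cout, cin, kh, kw = w.shape
        assert x.shape[0] == cin, f"channel mismatch {x.shape[0]} vs {cin}"
        H, W = x.shape[1], x.shape[2]
        oh, ow = H + 2 * padding - kh + 1, W + 2 * padding - kw + 1
        xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        # win: (cin, oh, ow, kh, kw) -> cols: (oh*ow, cin*kh*kw)
        cols = win.transpose(1, 2, 0, 3, 4).reshape(oh * ow, cin * kh * kw)
        wmat = w.reshape(cout, cin * kh * kw)
        y = (cols @ wmat.T + b).T.reshape(cout, oh, ow)
        out = Tensor(y, parents=(self, weight, bias))
        out.requires_grad = self._needs(weight, bias)

        def bw(g):
            gmat = g.reshape(cout, oh * ow).T  # (oh*ow, cout)
            weight._accum((gmat.T @ cols).reshape(w.shape))
            bias._accum(gmat.sum(axis=0))
            gcols = gmat @ wmat  # (oh*ow, cin*kh*kw)
            gcols = gcols.reshape(oh, ow, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + oh, j : j + ow] += gcols[:, :, :, i, j].transpose(
                        2, 0, 1
                    )
            if padding:
                gx = gxp[:, padding:-padding, padding:-padding]
            else:
                gx = gxp
            self._accum(gx)

        out._backward = bw
        return out

    def maxpool2(self):
        """2x2 max pooling with stride 2 on a (C, H, W) tensor."""
        c, H, W = self.data.shape
        assert H % 2 == 0 and W % 2 == 0, "maxpool2 needs even spatial dims"
        blocks = self.data.reshape(c, H // 2, 2, W // 2, 2)
        y = blocks.max(axis=(2, 4))
        out = Tensor(y, parents=(self,))
        out.requires_grad = self.requires_grad
        mask = blocks == y[:, :, None, :, None]
        # break ties: keep only first max per block
        flat = mask.transpose(0, 1, 3, 2, 4).reshape(c, H // 2, W // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(c, H // 2, W // 2, 2, 2).transpose(0, 1, 3, 2, 4)

        def bw(g):
            gb = mask * g[:, :, None, :, None]
            self._accum(gb.reshape(c, H, W))

        out._backward = bw
        return out

    def upsample2(self):
        """Nearest-neighbour 2x upsampling on a (C, H, W) tensor."""
        y = self.data.repeat(2, axis=1).repeat(2, axis=2)
        out = Tensor(y, parents=(self,))
        out.requires_grad = self.requires_grad
        c, H, W = self.data.shape

        def bw(g):
            self._accum(g.reshape(c, H, 2, W, 2).sum(axis=(2, 4)))

        out._backward = bw
        return out
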