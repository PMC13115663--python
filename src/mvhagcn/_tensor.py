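"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains a graph neural network on CPU; no autodiff framework is a
runtime dependency, so this module provides the small set of differentiable
operations the model needs (dense matmul, elementwise nonlinearities,
row-softmax, 1-D convolution, row gathering) plus an Adam optimizer.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = np.asarray(data, dtype=dtype)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other, dtype) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=dtype))

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = self._lift(other, self.dtype)
        return self + (-other)

    def __rsub__(self, other):
        return self._lift(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division is supported by scalars only")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return self._make(out_data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g.T)

        return self._make(self.data.T, (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, s=out_data):
            if a.requires_grad:
                a._accumulate(g * s * (1.0 - s))

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through unclipped entries."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, s=s, axis=axis):
            if a.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                a._accumulate(s * (g - dot))

        return self._make(s, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._make(self.data.sum(), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g, a=self, n=n):
            if a.requires_grad:
                a._accumulate(np.broadcast_to(g / n, a.data.shape).copy())

        return self._make(self.data.mean(), (self,), backward)

    # -- structural ops -------------------------------------------------------
    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Gather rows by integer index; backward scatters with accumulation."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]

        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, idx, g)
                a._accumulate(acc)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def conv1d_same(self, kernel: "Tensor") -> "Tensor":
        """1-D cross-correlation of a vector with odd-length kernel, same padding.

        Used by the channel-attention stage; `self` is a length-C vector and
        `kernel` a length-k vector with k odd.
        """
        x = self.data
        w = kernel.data
        k = w.shape[0]
        if k % 2 != 1:
            raise ValueError("kernel length must be odd")
        pad = k // 2
        xp = np.pad(x, pad)
        out_data = np.correlate(xp, w, mode="valid")

        def backward(g, a=self, kern=kernel, w=w, xp=xp, pad=pad):
            if a.requires_grad:
                gp = np.pad(g, pad)
                a._accumulate(np.correlate(gp, w[::-1], mode="valid"))
            if kern.requires_grad:
                kg = np.array(
                    [np.dot(xp[i : i + g.shape[0]], g) for i in range(w.shape[0])]
                )
                kern._accumulate(kg)

        return self._make(out_data, (self, kernel), backward)

    # -- autograd driver ------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis (used to join attention heads)."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g, parts=tuple(tensors), splits=splits, axis=axis):
            pieces = np.split(g, splits, axis=axis)
            for t, piece in zip(parts, pieces):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = backward
    return out


class Adam:
    """Adam with coupled (L2-style) weight decay, matching the common
    deep-learning default where decay is added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / b1t
            vhat = v / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
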