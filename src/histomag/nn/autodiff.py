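"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Scope is exactly what the Vision Transformer needs: broadcast add/mul,
batched matmul, reshape/transpose, layer normalization, softmax, GELU/ReLU,
dropout, token concatenation/selection, axis means and a fused softmax
cross-entropy loss.  Gradients accumulate into ``Tensor.grad`` after
``backward()`` on a scalar.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return Tensor(out_data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return Tensor(out_data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g @ other.data.swapaxes(-1, -2), self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(self.data.swapaxes(-1, -2) @ g, other.shape)

        return Tensor(out_data, parents=(self, other), backward=backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return Tensor(out_data, parents=(self,), backward=backward)

    def transpose(self, axes):
        inverse = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self.grad += g.transpose(inverse)

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean_axis(self, axis: int):
        n = self.shape[axis]
        out_data = self.data.mean(axis=axis)

        def backward(g):
            if self.requires_grad:
                self.grad += np.expand_dims(g, axis) / n

        return Tensor(out_data, parents=(self,), backward=backward)

    def take_token(self, index: int):
        """Select one token along axis 1: (B, N, D) -> (B, D)."""
        out_data = self.data[:, index]

        def backward(g):
            if self.requires_grad:
                self.grad[:, index] += g

        return Tensor(out_data, parents=(self,), backward=backward)

    @staticmethod
    def concat_token(token: "Tensor", x: "Tensor") -> "Tensor":
        """Prepend a (1, 1, D) learnable token to a (B, N, D) sequence."""
        b = x.shape[0]
        out_data = np.concatenate([np.broadcast_to(token.data, (b, 1, token.shape[2])), x.data], axis=1)

        def backward(g):
            if token.requires_grad:
                token.grad += g[:, :1].sum(axis=0, keepdims=True)
            if x.requires_grad:
                x.grad += g[:, 1:]

        return Tensor(out_data, parents=(token, x), backward=backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor(out_data, parents=(self,), backward=backward)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * cdf

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self.grad += g * (cdf + x * pdf)

        return Tensor(out_data, parents=(self,), backward=backward)

    def softmax(self):
        """Numerically stable softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            if self.requires_grad:
                self.grad += (g - (g * s).sum(axis=-1, keepdims=True)) * s

        return Tensor(s, parents=(self,), backward=backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-6):
        """Normalize the last axis, then scale/shift by gamma/beta."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out_data = gamma.data * xhat + beta.data

        def backward(g):
            if gamma.requires_grad:
                gamma.grad += _unbroadcast(g * xhat, gamma.shape)
            if beta.requires_grad:
                beta.grad += _unbroadcast(g, beta.shape)
            if self.requires_grad:
                gy = g * gamma.data
                self.grad += inv * (
                    gy
                    - gy.mean(axis=-1, keepdims=True)
                    - xhat * (gy * xhat).mean(axis=-1, keepdims=True)
                )

        return Tensor(out_data, parents=(self, gamma, beta), backward=backward)

    def dropout(self, p: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when rng is None (eval mode) or p == 0."""
        if rng is None or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor(out_data, parents=(self,), backward=backward)

    def cross_entropy(self, onehot: np.ndarray) -> "Tensor":
        """Mean categorical cross-entropy of logits against one-hot labels."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logsm = z - logsumexp
        n = self.shape[0]
        loss = -(onehot * logsm).sum() / n

        def backward(g):
            if self.requires_grad:
                self.grad += g * (np.exp(logsm) - onehot) / n

        return Tensor(loss, parents=(self,), backward=backward)
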