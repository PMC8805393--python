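"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the sequence models in :mod:`nntoc.models`
need: dense matmul, broadcast add/sub/mul, the sigmoid/tanh/relu
nonlinearities, column slicing (for fused LSTM gate blocks), and
sum/mean reductions.  Gradients flow through a topologically sorted tape;
broadcasting is handled by summing gradients back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "sigmoid", "tanh", "relu", "glorot"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the operand's shape before broadcast)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(-g, b.data.shape)

        return self._node(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return self._lift(other) - self

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += -g

        return self._node(-self.data, (self,), backward)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by plain scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += g @ b.data.T
            if b.requires_grad:
                b.grad += a.data.T @ g

        return self._node(self.data @ other.data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a.grad += g * (1.0 - y * y)

        return self._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a.grad += g * y * (1.0 - y)

        return self._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a.grad += g * m

        return self._node(self.data * mask, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def cols(self, start: int, stop: int):
        """Column slice ``[:, start:stop]`` (gate-block extraction)."""

        def backward(g, a=self, s=start, e=stop):
            if a.requires_grad:
                a.grad[:, s:e] += g

        return self._node(self.data[:, start:stop], (self,), backward)

    def sum(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g  # g is scalar, broadcasts

        return self._node(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g, a=self, n=n):
            if a.requires_grad:
                a.grad += g / n

        return self._node(self.data.mean(), (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS post-order
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


def sigmoid(t: Tensor) -> Tensor:
    return t.sigmoid()


def tanh(t: Tensor) -> Tensor:
    return t.tanh()


def relu(t: Tensor) -> Tensor:
    return t.relu()


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam with decoupled (AdamW-style) weight decay on matrix parameters."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
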