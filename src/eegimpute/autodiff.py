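"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order and accumulates gradients.  The operation set is exactly
what the attention encoder and the LSTM forecaster in this package need —
broadcast arithmetic, batched matmul, tanh/relu/sigmoid/exp, axis
reductions, reshape/swapaxes — nothing more.

Gradients of every op are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes of size 1 that were expanded
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- graph bookkeeping ---------------------------------------------------

    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:  # scalars adopt our dtype instead of upcasting
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs outgrow the recursion limit
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()   # release graph memory as we go
                node._backward = None

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(g)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accumulate(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g * b.data)
            if b.requires_grad:
                b._accumulate(g * a.data)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g / b.data)
            if b.requires_grad:
                b._accumulate(-g * a.data / b.data ** 2)
        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only constant exponents are supported")
        def backward(g, a=self, e=exponent):
            a._accumulate(g * e * a.data ** (e - 1))
        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        A, B = self.data, other.data
        if B.ndim == 2 and A.ndim > 2:
            # (..., m, k) @ (k, n): one flat GEMM beats numpy's batch loop
            lead = A.shape[:-1]
            A2 = A.reshape(-1, A.shape[-1])
            out = (A2 @ B).reshape(*lead, B.shape[1])
            def backward(g, a=self, b=other, A2=A2, B=B, lead=lead):
                g2 = g.reshape(-1, g.shape[-1])
                if a.requires_grad:
                    a._accumulate((g2 @ B.T).reshape(*lead, B.shape[0]))
                if b.requires_grad:
                    b._accumulate(A2.T @ g2)
            return self._make(out, (self, other), backward)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                b._accumulate(np.swapaxes(a.data, -1, -2) @ g)
        return self._make(A @ B, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, o=out_data):
            a._accumulate(g * o)
        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g, a=self, o=out_data):
            a._accumulate(g * (1.0 - o ** 2))
        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g, a=self, o=out_data):
            a._accumulate(g * o * (1.0 - o))
        return self._make(out_data, (self,), backward)

    def relu(self):
        keep = self.data > 0
        def backward(g, a=self, k=keep):
            a._accumulate(g * k)
        return self._make(np.where(keep, self.data, 0.0), (self,), backward)

    # -- reductions & shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = (self.data.size if axis is None
                 else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        hit = self.data == out_data
        hit = hit / hit.sum(axis=axis, keepdims=True)  # split ties evenly
        def backward(g, a=self, h=hit, ax=axis, kd=keepdims):
            if not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(g * h)
        return self._make(out_data if keepdims else out_data.squeeze(axis),
                          (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def backward(g, a=self, s=old):
            a._accumulate(g.reshape(s))
        return self._make(self.data.reshape(shape), (self,), backward)

    def narrow(self, start: int, stop: int):
        """Contiguous slice of the last axis."""
        width = self.data.shape[-1]
        def backward(g, a=self, s=start, e=stop, w=width):
            pad = np.zeros(g.shape[:-1] + (w,), dtype=g.dtype)
            pad[..., s:e] = g
            a._accumulate(pad)
        return self._make(self.data[..., start:stop], (self,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        def backward(g, a=self, i=ax1, j=ax2):
            a._accumulate(np.swapaxes(g, i, j))
        return self._make(np.swapaxes(self.data, ax1, ax2), (self,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (fused single op)."""
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    s = e / e.sum(axis=axis, keepdims=True)
    def backward(g, a=x, s=s, ax=axis):
        a._accumulate(s * (g - (g * s).sum(axis=ax, keepdims=True)))
    return x._make(s, (x,), backward)


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance (fused op).

    Gain and bias, if any, are applied by the caller with ordinary ops.
    """
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    def backward(g, a=x, y=y, inv=inv):
        a._accumulate(inv * (g - g.mean(axis=-1, keepdims=True)
                             - y * (g * y).mean(axis=-1, keepdims=True)))
    return x._make(y, (x,), backward)


def parameter(rng: np.random.Generator, *shape, scale: float | None = None,
              dtype=np.float32) -> Tensor:
    """Trainable tensor with Glorot-style initialisation."""
    if scale is None:
        fan_in = shape[-2] if len(shape) > 1 else shape[0]
        fan_out = shape[-1]
        scale = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, scale, size=shape).astype(dtype),
                  requires_grad=True)


def zeros_parameter(*shape, dtype=np.float32) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def ones_parameter(*shape, dtype=np.float32) -> Tensor:
    return Tensor(np.ones(shape, dtype=dtype), requires_grad=True)


class Adam:
    """Adam optimiser with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
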