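"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the small neural-network substrate the rest of the
package trains with: a :class:`Tensor` with a dynamic tape, the handful of
differentiable operations an autoregressive GRU policy and small MLPs need,
and an :class:`Adam` optimizer.  Everything is float64 and CPU-sized by
design — the models in this package are desk-scale recurrent nets, not
large language models.

Gradient correctness of every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gru_cell",
    "init_gru_params",
    "init_mlp_params",
    "log_softmax",
    "mlp_forward",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a backward closure on a dynamic tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- tape plumbing -----------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._result(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._result(self.data @ other.data, (self, other), backward)

    @property
    def T(self):
        def backward(g):
            self._accum(g.T)

        return Tensor._result(self.data.T, (self,), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        out_data = m + np.log(s)
        softmax = np.exp(self.data - out_data)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * softmax)

        return Tensor._result(out_data, (self,), backward)

    # -- indexing ----------------------------------------------------------

    def rows(self, idx: np.ndarray):
        """Gather rows (embedding lookup): out[i] = self[idx[i]]."""
        idx = np.asarray(idx)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            if self.grad is None:
                self.grad = full
            else:
                self.grad += full

        return Tensor._result(self.data[idx], (self,), backward)

    def select(self, idx: np.ndarray):
        """Pick one entry per row of a 2-D tensor: out[i] = self[i, idx[i]]."""
        idx = np.asarray(idx)
        rows = np.arange(self.data.shape[0])

        def backward(g):
            full = np.zeros_like(self.data)
            full[rows, idx] = g
            if self.grad is None:
                self.grad = full
            else:
                self.grad += full

        return Tensor._result(self.data[rows, idx], (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._result(self.data.reshape(*shape), (self,), backward)

    def logdet(self):
        """Log-determinant of a positive-definite matrix."""
        sign, ld = np.linalg.slogdet(self.data)
        if sign <= 0:
            raise np.linalg.LinAlgError("matrix is not positive definite")
        inv = np.linalg.inv(self.data)

        def backward(g):
            self._accum(g * inv.T)

        return Tensor._result(ld, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along an axis, splitting the gradient back."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    return x - x.logsumexp(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# parameter initialisation and layer application
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def init_gru_params(rng: np.random.Generator, input_size: int, hidden_size: int) -> dict[str, Tensor]:
    """One GRU layer: update (z), reset (r) and candidate (n) gates."""
    p: dict[str, Tensor] = {}
    for gate in ("z", "r", "n"):
        p[f"Wx{gate}"] = Tensor(_glorot(rng, input_size, hidden_size), requires_grad=True)
        p[f"Wh{gate}"] = Tensor(_glorot(rng, hidden_size, hidden_size), requires_grad=True)
        p[f"bx{gate}"] = Tensor(np.zeros(hidden_size), requires_grad=True)
        p[f"bh{gate}"] = Tensor(np.zeros(hidden_size), requires_grad=True)
    return p


def gru_cell(p: dict[str, Tensor], x: Tensor, h: Tensor) -> Tensor:
    """One GRU step: h' = (1 - z) * n + z * h.

    Gate convention matches the usual formulation with the reset gate
    applied to the hidden contribution of the candidate.
    """
    z = (x @ p["Wxz"] + p["bxz"] + h @ p["Whz"] + p["bhz"]).sigmoid()
    r = (x @ p["Wxr"] + p["bxr"] + h @ p["Whr"] + p["bhr"]).sigmoid()
    n = (x @ p["Wxn"] + p["bxn"] + r * (h @ p["Whn"] + p["bhn"])).tanh()
    return (1.0 - z) * n + z * h


def gru_cell_np(p: dict[str, Tensor], x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Graph-free twin of :func:`gru_cell` for fast sampling."""

    def sig(a):
        return 1.0 / (1.0 + np.exp(-a))

    d = {k: t.data for k, t in p.items()}
    z = sig(x @ d["Wxz"] + d["bxz"] + h @ d["Whz"] + d["bhz"])
    r = sig(x @ d["Wxr"] + d["bxr"] + h @ d["Whr"] + d["bhr"])
    n = np.tanh(x @ d["Wxn"] + d["bxn"] + r * (h @ d["Whn"] + d["bhn"]))
    return (1.0 - z) * n + z * h


def init_mlp_params(
    rng: np.random.Generator, sizes: list[int], prefix: str = "fc"
) -> dict[str, Tensor]:
    p: dict[str, Tensor] = {}
    for i, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:])):
        p[f"{prefix}{i}_W"] = Tensor(_glorot(rng, fi, fo), requires_grad=True)
        p[f"{prefix}{i}_b"] = Tensor(np.zeros(fo), requires_grad=True)
    return p


def mlp_forward(p: dict[str, Tensor], x: Tensor, n_layers: int, prefix: str = "fc") -> Tensor:
    """Feed-forward pass with ReLU between layers, linear output."""
    h = x
    for i in range(n_layers):
        h = h @ p[f"{prefix}{i}_W"] + p[f"{prefix}{i}_b"]
        if i < n_layers - 1:
            h = h.relu()
    return h


def mlp_forward_np(p: dict[str, Tensor], x: np.ndarray, n_layers: int, prefix: str = "fc") -> np.ndarray:
    """Graph-free twin of :func:`mlp_forward`."""
    h = np.asarray(x, dtype=np.float64)
    for i in range(n_layers):
        h = h @ p[f"{prefix}{i}_W"].data + p[f"{prefix}{i}_b"].data
        if i < n_layers - 1:
            h = np.maximum(h, 0.0)
    return h


class Adam:
    """Adam with bias correction, operating in place on Tensor params."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
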