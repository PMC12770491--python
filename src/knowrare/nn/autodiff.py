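"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains three differentiable components — a recurrent time-series
encoder, an outcome classifier and a multi-domain discriminator — at desk
scale (batches of tens to hundreds, hidden sizes of tens). A small tape-based
autodiff engine is sufficient for that and keeps the package free of deep
learning framework dependencies.

Only the operations the models need are implemented. Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which walks the
tape in reverse topological order. Cross-entropy losses are fused
(log-sum-exp based) for numerical stability.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "grad_reverse",
    "sigmoid",
    "softmax",
    "softmax_cross_entropy",
    "binary_cross_entropy_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting added or stretched."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def _wrap(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            return (g @ other.data.T, self.data.T @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bw
    return out


def grad_reverse(x: Tensor, scale: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-scale``.

    Realises the adversarial minimax: the discriminator loss is minimised with
    respect to discriminator parameters while the encoder (upstream of this
    node) receives the sign-reversed gradient, i.e. maximises domain confusion.
    """
    out = Tensor(x.data, _parents=(x,))
    out._backward = lambda g: (-scale * g,)
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, _parents=(x,))
    out._backward = lambda g: (g * y * (1.0 - y),)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    out._backward = bw
    return out


def _log_softmax(z: np.ndarray) -> np.ndarray:
    m = z.max(axis=-1, keepdims=True)
    return z - m - np.log(np.exp(z - m).sum(axis=-1, keepdims=True))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, sample_weight=None) -> Tensor:
    """Weighted mean categorical cross-entropy over a batch of logits.

    ``labels`` are integer class indices; ``sample_weight`` multiplies each
    sample's loss term before the batch mean (defaults to 1).
    """
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    logp = _log_softmax(logits.data)
    losses = -logp[np.arange(n), labels]
    out = Tensor(np.array((w * losses).mean()), _parents=(logits,))

    def bw(g):
        p = np.exp(logp)
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        return (float(g) * grad * (w / n)[:, None],)

    out._backward = bw
    return out


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray, sample_weight=None) -> Tensor:
    """Weighted mean binary cross-entropy; multi-label inputs sum over labels.

    ``logits`` has shape (n,) or (n, L); a sample's loss is the sum of its
    per-label terms, weighted by ``sample_weight`` and averaged over the batch.
    """
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    n = z.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    # stable: max(z,0) - z*t + log(1+exp(-|z|))
    per = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    per_sample = per if per.ndim == 1 else per.sum(axis=-1)
    out = Tensor(np.array((w * per_sample).mean()), _parents=(logits,))

    def bw(g):
        p = 1.0 / (1.0 + np.exp(-z))
        grad = (p - t) * (w / n if z.ndim == 1 else (w / n)[:, None])
        return (float(g) * grad,)

    out._backward = bw
    return out
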