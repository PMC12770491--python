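"""Neural building blocks: linear layers, MLPs, an LSTM and Adam.

Parameter initialisation draws from an explicit ``numpy.random.Generator`` so
that every model in the package is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, sigmoid

__all__ = ["Module", "Linear", "MLP", "LSTM", "Adam"]


class Module:
    """Base class: a named, ordered collection of parameter tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = s.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Tensor.param(_glorot(rng, in_dim, out_dim))
        self.b = Tensor.param(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Fully-connected network with tanh hidden activations, linear output."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh()
        return x


class LSTM(Module):
    """Single-layer LSTM; processes a (batch, T, V) array, returns hidden states.

    Gate order in the stacked weight matrices is input, forget, cell, output.
    The forget-gate bias starts at 1 (standard practice, aids gradient flow on
    short clinical windows).
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.hidden = hidden
        self.Wx = Tensor.param(_glorot(rng, in_dim, 4 * hidden))
        self.Wh = Tensor.param(_glorot(rng, hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Tensor.param(b)

    def __call__(self, x: np.ndarray) -> list[Tensor]:
        """Run the recurrence; returns the list [h_1, ..., h_T] (batch, hidden)."""
        x = np.asarray(x, dtype=np.float64)
        batch, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        outputs: list[Tensor] = []
        for t in range(T):
            xt = Tensor(x[:, t, :])
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(gates[:, 0:H])
            f = sigmoid(gates[:, H : 2 * H])
            g = gates[:, 2 * H : 3 * H].tanh()
            o = sigmoid(gates[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h)
        return outputs


class Adam(Module):
    """Adam optimiser with fixed hyperparameters over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
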