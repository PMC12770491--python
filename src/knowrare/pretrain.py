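"""Condition-agnostic self-supervised pre-training of the time-series encoder.

The encoder fuses a recurrent temporal branch with a static context branch:

    h_t = f_proj(f_temp(x_t), f_cont(C)),

where f_temp is a single-layer LSTM over the binned variable grid X, f_cont
a one-hidden-layer network over the demographic context C (encoded once and
fused at every step), and f_proj a linear projection with tanh producing the
latent h_t. Pre-training minimises next-step trajectory reconstruction,

    L = 1/(T-1) * sum_{t=1}^{T-1} || X_{t+1} - f_dec(h_t) ||^2,

averaged over patients of *all* conditions, so the learned dynamics are not
specific to any one condition. The final hidden state h_T later serves as the
patient representation for outcome prediction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PretrainConfig, spawn_rng
from .nn import LSTM, MLP, Adam, Linear, Module, Tensor, concat

logger = logging.getLogger(__name__)

__all__ = ["Encoder", "next_step_loss", "pretrain", "save_encoder", "load_encoder"]


class Encoder(Module):
    """Temporal + contextual encoder with projection and next-step decoder."""

    def __init__(self, n_variables: int, context_dim: int, hidden_size: int = 32,
                 context_size: int = 16, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.n_variables = n_variables
        self.hidden_size = hidden_size
        self.temporal = LSTM(n_variables, hidden_size, rng)
        self.contextual = MLP([context_dim, context_size, context_size], rng)
        self.projection = Linear(hidden_size + context_size, hidden_size, rng)
        self.decoder = Linear(hidden_size, n_variables, rng)

    def encode(self, X: np.ndarray, C: np.ndarray) -> list[Tensor]:
        """Hidden sequence [h_1 .. h_T], each (batch, hidden_size)."""
        if np.isnan(X).any() or np.isnan(C).any():
            raise ValueError("encoder inputs must be imputed (no NaN)")
        ctx = self.contextual(Tensor(C)).tanh()
        return [self.projection(concat([h, ctx], axis=-1)).tanh()
                for h in self.temporal(X)]

    def final_state(self, X: np.ndarray, C: np.ndarray) -> Tensor:
        return self.encode(X, C)[-1]


def next_step_loss(encoder: Encoder, X: np.ndarray, C: np.ndarray) -> Tensor:
    """Mean over t of squared L2 next-step reconstruction error, batch-averaged."""
    X = np.asarray(X, dtype=float)
    T = X.shape[1]
    if T < 2:
        raise ValueError("next-step loss requires at least 2 time steps")
    hs = encoder.encode(X, C)
    total = None
    for t in range(T - 1):
        pred = encoder.decoder(hs[t])
        diff = pred - Tensor(X[:, t + 1, :])
        term = (diff * diff).sum(axis=1)
        total = term if total is None else total + term
    return (total * (1.0 / (T - 1))).mean()


def pretrain(X: np.ndarray, C: np.ndarray, config: PretrainConfig,
             X_val: np.ndarray | None = None, C_val: np.ndarray | None = None,
             conditions: np.ndarray | None = None) -> tuple[Encoder, pd.DataFrame]:
    """Fit the encoder by next-step prediction over every training patient.

    Returns the encoder (parameters of the best validation epoch when a
    validation set is given, else the final epoch) and the training curve.
    ``conditions`` is optional instrumentation: distinct condition codes seen
    are logged to make the condition-agnostic contract auditable.
    """
    if len(X) == 0:
        raise ValueError("cannot pre-train on an empty dataset")
    if conditions is not None:
        logger.info("pretrain: %d patients across %d distinct conditions",
                    len(X), len(np.unique(conditions)))
    init_rng = spawn_rng(config.seed, "pretrain-init")
    batch_rng = spawn_rng(config.seed, "pretrain-batches")
    encoder = Encoder(X.shape[2], C.shape[1], config.hidden_size,
                      config.context_size, init_rng)
    opt = Adam(encoder.parameters(), lr=config.learning_rate)

    history = []
    best_val, best_state, patience_left = np.inf, None, config.patience
    n = len(X)
    for epoch in range(config.epochs):
        order = batch_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = next_step_loss(encoder, X[idx], C[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        row = {"epoch": epoch, "train_loss": epoch_loss / n}
        if X_val is not None and len(X_val):
            val = float(next_step_loss(encoder, X_val, C_val).data)
            row["val_loss"] = val
            if val < best_val - 1e-9:
                best_val, best_state, patience_left = val, encoder.state(), config.patience
            else:
                patience_left -= 1
        history.append(row)
        if X_val is not None and patience_left <= 0:
            logger.info("pretrain: early stop at epoch %d", epoch)
            break
    if best_state is not None:
        encoder.load_state(best_state)
    return encoder, pd.DataFrame(history)


def save_encoder(encoder: Encoder, path, seed: int | None = None) -> None:
    """Checkpoint: parameter blobs plus the architecture needed to rebuild."""
    meta = dict(
        n_variables=encoder.n_variables,
        context_dim=encoder.contextual.layers[0].W.data.shape[0],
        hidden_size=encoder.hidden_size,
        context_size=encoder.contextual.layers[-1].W.data.shape[1],
        seed=-1 if seed is None else seed,
        version=1,
    )
    state = {f"param_{i}": arr for i, arr in enumerate(encoder.state())}
    np.savez(path, **state, **{f"meta_{k}": v for k, v in meta.items()})


def load_encoder(path) -> Encoder:
    blob = np.load(path)
    enc = Encoder(int(blob["meta_n_variables"]), int(blob["meta_context_dim"]),
                  int(blob["meta_hidden_size"]), int(blob["meta_context_size"]))
    n_params = len([k for k in blob.files if k.startswith("param_")])
    enc.load_state([blob[f"param_{i}"] for i in range(n_params)])
    return enc
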