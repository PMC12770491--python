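"""Joint adversarial domain adaptation onto a target rare condition.

The pre-trained encoder is fine-tuned on the target condition together with
its selected source conditions. A classifier head f_theta maps the final
latent state h_T to outcome probabilities y_hat; a discriminator d_phi maps
the concatenation (h_T, y_hat) to a distribution over the |S*|+1 domains
(target plus one domain per source condition). Training alternates:

* discriminator step — phi minimises the multi-class cross-entropy of the
  domain prediction on detached (h_T, y_hat);
* model step — theta minimises L_pred + lambda * L_adv where the adversarial
  gradient reaching the encoder and classifier is sign-reversed (the
  gradient-reversal realisation of the minimax game), so the encoder learns
  representations whose joint (h_T, y_hat) distribution the discriminator
  cannot separate.

The prediction loss is cross-entropy with inverse-propensity sample weights
w_v = 1/p(v), p(v) the training prevalence of the sample's condition
(normalised to mean 1 over the pool by default), so rare conditions are not
drowned out by common sources. Model selection keeps the epoch with the best
target-validation AUPRC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AdaptConfig, TaskSpec, spawn_rng
from .metrics import auprc
from .nn import (MLP, Adam, Linear, Module, Tensor, binary_cross_entropy_with_logits,
                 concat, grad_reverse, sigmoid, softmax, softmax_cross_entropy)
from .pretrain import Encoder

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledData",
    "AdaptModel",
    "AdaptResult",
    "propensity_weights",
    "classify",
    "adversarial_loss",
    "weighted_prediction_loss",
    "total_loss",
    "predict_scores",
    "fine_tune",
    "adapt",
]


@dataclass
class LabeledData:
    """A set of stays: tensors X (n, T, V), context C (n, d_c), labels y and
    the level-3 condition code per stay."""

    X: np.ndarray
    C: np.ndarray
    y: np.ndarray
    condition: np.ndarray

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "LabeledData":
        return LabeledData(self.X[idx], self.C[idx], self.y[idx], self.condition[idx])

    @staticmethod
    def concatenate(parts: list["LabeledData"]) -> "LabeledData":
        return LabeledData(np.concatenate([p.X for p in parts]),
                           np.concatenate([p.C for p in parts]),
                           np.concatenate([p.y for p in parts]),
                           np.concatenate([p.condition for p in parts]))


class AdaptModel(Module):
    def __init__(self, encoder: Encoder, task: TaskSpec,
                 n_domains: int = 1, discriminator_hidden: int = 64,
                 rng: np.random.Generator | None = None,
                 disc_rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.encoder = encoder
        self.task = task
        self.classifier = Linear(encoder.hidden_size, task.n_outputs, rng)
        self.n_domains = n_domains
        self.discriminator = None
        if n_domains > 1:
            self.discriminator = MLP([encoder.hidden_size + task.n_outputs,
                                      discriminator_hidden, n_domains],
                                     disc_rng if disc_rng is not None else rng)

    def model_parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.classifier.parameters()


def propensity_weights(prevalence: dict[str, float], conditions: np.ndarray,
                       normalize: bool = True) -> np.ndarray:
    """Per-sample inverse propensity weights w_v = 1/p(v); unknown conditions
    are a configuration error. With ``normalize`` the weights are rescaled to
    mean 1 over the given samples."""
    missing = set(np.unique(conditions)) - set(prevalence)
    if missing:
        raise KeyError(f"no prevalence for conditions: {sorted(missing)}")
    w = np.array([1.0 / prevalence[c] for c in conditions])
    return w / w.mean() if normalize else w


def classify(model: AdaptModel, h_T: Tensor) -> tuple[Tensor, Tensor]:
    """Classifier logits and probabilities for the task head."""
    logits = model.classifier(h_T)
    if model.task.label_kind == "multiclass":
        probs = softmax(logits, axis=-1)
    else:
        probs = sigmoid(logits)
    return logits, probs


def adversarial_loss(model: AdaptModel, h_T: Tensor, y_hat: Tensor,
                     domains: np.ndarray, reverse: bool = False) -> Tensor:
    """Multi-class domain cross-entropy of d_phi(h_T, y_hat), batch-averaged.

    With ``reverse`` the gradient flowing back into (h_T, y_hat) — and hence
    the encoder and classifier — is sign-flipped.
    """
    if model.discriminator is None:
        raise ValueError("model has no discriminator")
    domains = np.asarray(domains)
    if domains.min() < 0 or domains.max() >= model.n_domains:
        raise ValueError("domain label outside range")
    joint = concat([h_T, y_hat], axis=-1)
    if reverse:
        joint = grad_reverse(joint)
    return softmax_cross_entropy(model.discriminator(joint), domains)


def weighted_prediction_loss(model: AdaptModel, logits: Tensor, y: np.ndarray,
                             sample_weight: np.ndarray | None = None) -> Tensor:
    """Task cross-entropy with per-sample inverse-propensity weights.

    binary: BCE; multiclass: categorical CE; multilabel: sum of per-label BCE.
    """
    kind = model.task.label_kind
    if kind == "binary":
        return binary_cross_entropy_with_logits(
            logits.reshape(-1), np.asarray(y, dtype=float), sample_weight)
    if kind == "multiclass":
        return softmax_cross_entropy(logits, np.asarray(y, dtype=int), sample_weight)
    return binary_cross_entropy_with_logits(logits, np.asarray(y, dtype=float),
                                            sample_weight)


def total_loss(pred: Tensor, adv: Tensor | None, lambda_adv: float) -> Tensor:
    """L_total = L_pred + lambda * L_adv."""
    if adv is None or lambda_adv == 0:
        return pred
    return pred + lambda_adv * adv


def predict_scores(model: AdaptModel, X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Outcome probabilities as a plain array: (n,) binary, else (n, L)."""
    h_T = model.encoder.final_state(X, C)
    _, probs = classify(model, h_T)
    out = probs.data
    return out[:, 0] if model.task.label_kind == "binary" else out


def _val_auprc(model: AdaptModel, val: LabeledData) -> float:
    scores = predict_scores(model, val.X, val.C)
    try:
        return auprc(scores, val.y)
    except ValueError:  # single-class validation labels: uninformative epoch
        return 0.0


@dataclass
class AdaptResult:
    model: AdaptModel
    history: pd.DataFrame
    best_epoch: int
    selection: list[str] = field(default_factory=list)


def _batches(order: np.ndarray, batch_size: int):
    for start in range(0, len(order), batch_size):
        yield order[start:start + batch_size]


def _ensure_target(idx: np.ndarray, is_target: np.ndarray, target_idx: np.ndarray,
                   min_count: int, rng: np.random.Generator) -> np.ndarray:
    """Swap random members for target samples when a batch has too few."""
    have = int(is_target[idx].sum())
    if have >= min_count:
        return idx
    need = min(min_count, len(idx)) - have
    replace_pos = rng.choice(np.flatnonzero(~is_target[idx]), size=need, replace=False)
    new = idx.copy()
    new[replace_pos] = rng.choice(target_idx, size=need, replace=True)
    return new


def fine_tune(train: LabeledData, target_val: LabeledData,
              encoder_init: Encoder | None, task: TaskSpec, config: AdaptConfig,
              n_variables: int | None = None, context_dim: int | None = None,
              sample_weight: np.ndarray | None = None) -> AdaptResult:
    """Plain supervised fine-tuning (no sources, no discriminator).

    Used for the target-only and pool-all baselines; also the exact reduction
    of :func:`adapt` at lambda = 0 with an empty source set.
    """
    encoder = _init_encoder(encoder_init, train, task, config, n_variables, context_dim)
    model = AdaptModel(encoder, task, n_domains=1,
                       rng=spawn_rng(config.seed, "fit-classifier-init"))
    opt = Adam(model.model_parameters(), lr=config.learning_rate)
    batch_rng = spawn_rng(config.seed, "fit-batches")

    history, best, best_state = [], -np.inf, None
    for epoch in range(config.epochs):
        order = batch_rng.permutation(len(train))
        ep_loss = 0.0
        for idx in _batches(order, config.batch_size):
            batch = train.subset(idx)
            w = sample_weight[idx] if sample_weight is not None else None
            h_T = model.encoder.final_state(batch.X, batch.C)
            logits, _ = classify(model, h_T)
            loss = weighted_prediction_loss(model, logits, batch.y, w)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
        val_auprc = _val_auprc(model, target_val)
        history.append({"epoch": epoch, "pred_loss": ep_loss / len(train),
                        "val_auprc": val_auprc})
        if val_auprc > best:
            best, best_state = val_auprc, model.state()
    best_epoch = int(np.argmax([h["val_auprc"] for h in history]))
    if best_state is not None:
        model.load_state(best_state)
    return AdaptResult(model, pd.DataFrame(history), best_epoch)


def _init_encoder(encoder_init, train, task, config, n_variables, context_dim) -> Encoder:
    if encoder_init is not None:
        enc = Encoder(encoder_init.n_variables,
                      encoder_init.contextual.layers[0].W.data.shape[0],
                      encoder_init.hidden_size,
                      encoder_init.contextual.layers[-1].W.data.shape[1])
        enc.load_state(encoder_init.state())
        return enc
    V = n_variables if n_variables is not None else train.X.shape[2]
    d_c = context_dim if context_dim is not None else train.C.shape[1]
    # hidden sizes follow the pretrain defaults when training from scratch
    return Encoder(V, d_c, hidden_size=32, context_size=16,
                   rng=spawn_rng(config.seed, "fit-encoder-init"))


def adapt(target_train: LabeledData, source_train: dict[str, LabeledData],
          target_val: LabeledData, encoder_init: Encoder | None,
          prevalence: dict[str, float], task: TaskSpec,
          config: AdaptConfig) -> AdaptResult:
    """Adversarial fine-tuning on target + selected source conditions.

    ``source_train`` maps each selected source condition to its training
    stays; an empty dict reduces to target-only fine-tuning (logged). Domain
    label 0 is the target, 1..k the sources in sorted-code order.
    """
    if len(target_train) == 0:
        raise ValueError("empty target training set")
    sources = dict(sorted(source_train.items()))
    if not sources:
        logger.info("adapt: no source conditions; reduces to target-only fine-tuning")
    parts = [target_train] + list(sources.values())
    pool = LabeledData.concatenate(parts)
    domains = np.concatenate([np.full(len(p), d, dtype=int)
                              for d, p in enumerate(parts)])
    n_domains = len(parts)
    weights = (propensity_weights(prevalence, pool.condition, config.normalize_weights)
               if prevalence else np.ones(len(pool)))

    encoder = _init_encoder(encoder_init, pool, task, config, None, None)
    model = AdaptModel(encoder, task, n_domains=n_domains,
                       discriminator_hidden=config.discriminator_hidden,
                       rng=spawn_rng(config.seed, "fit-classifier-init"),
                       disc_rng=spawn_rng(config.seed, "fit-disc-init"))
    model_opt = Adam(model.model_parameters(), lr=config.learning_rate)
    disc_opt = (Adam(model.discriminator.parameters(), lr=config.discriminator_lr)
                if model.discriminator is not None else None)
    batch_rng = spawn_rng(config.seed, "fit-batches")
    strat_rng = spawn_rng(config.seed, "fit-stratify")

    is_target = domains == 0
    target_idx = np.flatnonzero(is_target)
    min_target = max(1, int(round(config.min_target_fraction
                                  * min(config.batch_size, len(pool))
                                  * len(target_train) / len(pool))))
    # every batch carries at least one target sample
    min_target = max(min_target, 1)

    history, best, best_state = [], -np.inf, None
    for epoch in range(config.epochs):
        order = batch_rng.permutation(len(pool))
        ep_pred, ep_adv, ep_disc = 0.0, 0.0, 0.0
        for idx in _batches(order, config.batch_size):
            idx = _ensure_target(idx, is_target, target_idx, min_target, strat_rng)
            batch = pool.subset(idx)
            dom = domains[idx]
            w = weights[idx]

            h_T = model.encoder.final_state(batch.X, batch.C)
            logits, probs = classify(model, h_T)

            if model.discriminator is not None:
                # discriminator step on detached joint features
                d_loss = adversarial_loss(model, h_T.detach(), probs.detach(), dom)
                disc_opt.zero_grad()
                d_loss.backward()
                disc_opt.step()
                ep_disc += float(d_loss.data) * len(idx)

            pred = weighted_prediction_loss(model, logits, batch.y, w)
            adv = None
            if model.discriminator is not None and config.lambda_adv > 0:
                adv = adversarial_loss(model, h_T, probs, dom, reverse=True)
                ep_adv += float(adv.data) * len(idx)
            loss = total_loss(pred, adv, config.lambda_adv)
            model_opt.zero_grad()
            if disc_opt is not None:
                disc_opt.zero_grad()  # discard spurious adversarial grads on phi
            loss.backward()
            model_opt.step()
            ep_pred += float(pred.data) * len(idx)

        val_auprc = _val_auprc(model, target_val)
        history.append({"epoch": epoch, "pred_loss": ep_pred / len(pool),
                        "adv_loss": ep_adv / len(pool),
                        "disc_loss": ep_disc / len(pool),
                        "val_auprc": val_auprc})
        if val_auprc > best:
            best, best_state = val_auprc, model.state()
    best_epoch = int(np.argmax([h["val_auprc"] for h in history]))
    if best_state is not None:
        model.load_state(best_state)
    return AdaptResult(model, pd.DataFrame(history), best_epoch,
                       selection=list(sources))
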