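"""Adversarial adaptation: loss definitions against loop oracles, propensity
weighting, head behaviour and the supervised-fine-tuning reduction."""

import numpy as np
import pandas as pd
import pytest

from knowrare.adapt import (AdaptModel, LabeledData, adapt, adversarial_loss,
                            classify, fine_tune, propensity_weights,
                            total_loss, weighted_prediction_loss)
from knowrare.config import AdaptConfig, TaskSpec
from knowrare.nn import Tensor
from knowrare.pretrain import Encoder


def _model(rng, task_name="icu_mortality", n_domains=3, V=4, d_c=2, hidden=6):
    enc = Encoder(V, d_c, hidden_size=hidden, context_size=3, rng=rng)
    return AdaptModel(enc, TaskSpec.named(task_name), n_domains=n_domains,
                      discriminator_hidden=8, rng=rng, disc_rng=rng)


def _batch(rng, n=12, V=4, d_c=2, task="icu_mortality"):
    X = rng.normal(size=(n, 8, V))
    C = rng.normal(size=(n, d_c))
    if task == "remaining_los":
        y = rng.integers(0, 10, size=n)
    elif task == "phenotyping":
        y = rng.integers(0, 2, size=(n, 25))
    else:
        y = rng.integers(0, 2, size=n)
    return LabeledData(X, C, y, np.array(["428"] * n))


class TestClassify:
    def test_multiclass_probabilities_sum_to_one(self, rng):
        model = _model(rng, "remaining_los")
        h = Tensor(rng.normal(size=(5, 6)))
        _, probs = classify(model, h)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_multilabel_probabilities_in_unit_interval(self, rng):
        model = _model(rng, "phenotyping")
        _, probs = classify(model, Tensor(rng.normal(size=(5, 6))))
        assert probs.data.shape == (5, 25)
        assert ((probs.data >= 0) & (probs.data <= 1)).all()

    def test_zeroed_softmax_head_is_uniform(self, rng):
        model = _model(rng, "remaining_los")
        model.classifier.W.data[:] = 0
        model.classifier.b.data[:] = 0
        _, probs = classify(model, Tensor(rng.normal(size=(3, 6))))
        np.testing.assert_allclose(probs.data, 0.1)


class TestAdversarialLoss:
    def test_uniform_discriminator_closed_form(self, rng):
        for n_domains in (2, 3, 5):
            model = _model(rng, n_domains=n_domains)
            final = model.discriminator.layers[-1]
            final.W.data[:] = 0
            final.b.data[:] = 0
            h = Tensor(rng.normal(size=(7, 6)))
            y_hat = Tensor(rng.uniform(size=(7, 1)))
            doms = rng.integers(0, n_domains, size=7)
            loss = adversarial_loss(model, h, y_hat, doms)
            np.testing.assert_allclose(float(loss.data), np.log(n_domains), rtol=1e-12)

    def test_perfect_discriminator_zero_loss(self, rng):
        model = _model(rng, n_domains=2)
        final = model.discriminator.layers[-1]
        final.W.data[:] = 0
        final.b.data[:] = [60.0, -60.0]
        loss = adversarial_loss(model, Tensor(rng.normal(size=(4, 6))),
                                Tensor(rng.uniform(size=(4, 1))), np.zeros(4, dtype=int))
        assert float(loss.data) < 1e-8

    def test_matches_per_sample_loop(self, rng):
        model = _model(rng, n_domains=4)
        h = Tensor(rng.normal(size=(9, 6)))
        y_hat = Tensor(rng.uniform(size=(9, 1)))
        doms = rng.integers(0, 4, size=9)
        got = float(adversarial_loss(model, h, y_hat, doms).data)
        joint = np.concatenate([h.data, y_hat.data], axis=1)
        logits = model.discriminator(Tensor(joint)).data
        expected = 0.0
        for i in range(9):
            z = logits[i] - logits[i].max()
            logp = z - np.log(np.exp(z).sum())
            expected -= logp[doms[i]]
        np.testing.assert_allclose(got, expected / 9, atol=1e-8)

    def test_domain_label_out_of_range(self, rng):
        model = _model(rng, n_domains=2)
        with pytest.raises(ValueError):
            adversarial_loss(model, Tensor(np.zeros((1, 6))),
                             Tensor(np.zeros((1, 1))), np.array([5]))


class TestWeightedPredictionLoss:
    def test_inverse_prevalence_weights(self):
        w = propensity_weights({"a": 0.9, "b": 0.1}, np.array(["a", "b"]),
                               normalize=False)
        np.testing.assert_allclose(w, [1 / 0.9, 10.0])

    def test_weight_equivariance_under_relabelling(self):
        """Swapping which condition is rarer permutes the weights."""
        prev = {"a": 0.8, "b": 0.2}
        swapped = {"a": 0.2, "b": 0.8}
        conds = np.array(["a", "b", "a"])
        relabelled = np.array(["b", "a", "b"])
        w1 = propensity_weights(prev, conds, normalize=False)
        w2 = propensity_weights(swapped, relabelled, normalize=False)
        np.testing.assert_allclose(w1, w2)

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            propensity_weights({"a": 1.0}, np.array(["b"]))

    def test_normalized_weights_mean_one(self):
        w = propensity_weights({"a": 0.9, "b": 0.1}, np.array(["a", "a", "b"]))
        np.testing.assert_allclose(w.mean(), 1.0)

    def test_perfect_predictions_zero_loss(self, rng):
        model = _model(rng)
        model.classifier.W.data[:] = 0
        y = np.array([1, 0, 1])
        logits = Tensor(np.array([[40.0], [-40.0], [40.0]]))
        loss = weighted_prediction_loss(model, logits, y, np.array([5.0, 1.0, 2.0]))
        assert float(loss.data) < 1e-8

    @pytest.mark.parametrize("task", ["icu_mortality", "remaining_los", "phenotyping"])
    def test_matches_per_sample_loop(self, rng, task):
        model = _model(rng, task)
        batch = _batch(rng, task=task)
        h = model.encoder.final_state(batch.X, batch.C)
        logits, _ = classify(model, h)
        w = rng.uniform(0.5, 3.0, size=len(batch))
        got = float(weighted_prediction_loss(model, logits, batch.y, w).data)
        z = logits.data
        expected = 0.0
        for i in range(len(batch)):
            if task == "remaining_los":
                zz = z[i] - z[i].max()
                logp = zz - np.log(np.exp(zz).sum())
                expected += -w[i] * logp[batch.y[i]]
            else:
                zi = np.atleast_1d(z[i])
                yi = np.atleast_1d(batch.y[i]).astype(float)
                p = 1 / (1 + np.exp(-zi))
                expected += w[i] * (-(yi * np.log(p) + (1 - yi) * np.log(1 - p))).sum()
        np.testing.assert_allclose(got, expected / len(batch), atol=1e-8)


class TestTotalLoss:
    def test_composition(self):
        pred, adv = Tensor(np.array(0.4)), Tensor(np.array(0.2))
        assert float(total_loss(pred, adv, 0.0).data) == 0.4
        np.testing.assert_allclose(float(total_loss(pred, adv, 0.5).data), 0.5)
        assert float(total_loss(pred, None, 1.0).data) == 0.4


class TestReduction:
    def test_adapt_without_sources_equals_fine_tuning(self, rng):
        """lambda=0 with no sources reproduces plain supervised fine-tuning
        step for step (identical loss trace under the same seed)."""
        task = TaskSpec.named("icu_mortality")
        train = _batch(rng, n=40)
        val = _batch(rng, n=16)
        enc = Encoder(4, 2, hidden_size=6, context_size=3,
                      rng=np.random.default_rng(9))
        cfg = AdaptConfig(lambda_adv=0.0, epochs=3, batch_size=16, seed=11)
        prevalence = {"428": 1.0}
        res_adapt = adapt(train, {}, val, enc, prevalence, task, cfg)
        w = propensity_weights(prevalence, train.condition)
        res_ft = fine_tune(train, val, enc, task, cfg, sample_weight=w)
        pd.testing.assert_series_equal(res_adapt.history["pred_loss"],
                                       res_ft.history["pred_loss"])
        np.testing.assert_array_equal(res_adapt.history["val_auprc"],
                                      res_ft.history["val_auprc"])

    def test_empty_target_rejected(self, rng):
        task = TaskSpec.named("icu_mortality")
        empty = _batch(rng, n=12).subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            adapt(empty, {}, _batch(rng, n=4), None, {}, task, AdaptConfig())
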