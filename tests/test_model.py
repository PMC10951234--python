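"""Backbone, heads, and the integrated loss."""

import numpy as np
import pytest

from stresslearn import (
    BackboneConfig,
    ColdStartError,
    LossTerms,
    LossWeights,
    StressModel,
    TrainConfig,
    generic_loss_weight,
    integrated_loss,
    merge_to_binary,
    train_model,
)
from stresslearn.model import POOLED


@pytest.fixture(scope="module")
def model(tiny_dataset, small_backbone):
    n, C, T, H = tiny_dataset.X.shape
    return StressModel(C, H, tiny_dataset.covariates.shape[1],
                       tiny_dataset.subject_list, config=small_backbone, seed=0)


class TestLossAlgebra:
    def test_weighted_sum_arithmetic(self):
        # alpha*RE + beta*CE_p + lambda*CE_g with the shipped defaults and
        # lambda = 1/22: 1e-4*2 + 1*1 + 0.5/22
        w = LossWeights(alpha=1e-4, beta=1.0, lam=1 / 22)
        val = integrated_loss(LossTerms(2.0, 1.0, 0.5), w, with_generic=True)
        assert val == pytest.approx(2e-4 + 1.0 + 0.5 / 22)

    def test_zero_alpha_removes_reconstruction_term(self):
        w = LossWeights(alpha=0.0, beta=1.0)
        assert integrated_loss(LossTerms(123.0, 0.7), w) == pytest.approx(0.7)

    def test_linear_in_each_term(self):
        w = LossWeights(alpha=0.5, beta=0.25, lam=0.1)
        base = integrated_loss(LossTerms(1.0, 1.0, 1.0), w, with_generic=True)
        bumped = integrated_loss(LossTerms(3.0, 1.0, 1.0), w, with_generic=True)
        assert bumped - base == pytest.approx(0.5 * 2.0)

    def test_default_weights(self):
        w = LossWeights()
        assert w.alpha == pytest.approx(1e-4) and w.beta == 1.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=2.0)
        with pytest.raises(ValueError):
            LossWeights(lam=0.0)

    def test_generic_weight_is_one_over_training_subjects(self):
        assert generic_loss_weight(22) == pytest.approx(1 / 22)
        with pytest.raises(ValueError):
            generic_loss_weight(0)


class TestMergeToBinary:
    def test_pure_negative(self):
        np.testing.assert_allclose(merge_to_binary(np.array([1.0, 0, 0])), [1, 0])

    def test_median_and_above_pool_to_positive(self):
        np.testing.assert_allclose(merge_to_binary(np.array([0.2, 0.5, 0.3])),
                                   [0.2, 0.8])

    def test_mass_conserved(self, rng):
        p = rng.dirichlet(np.ones(3), size=50)
        out = merge_to_binary(p)
        np.testing.assert_allclose(out.sum(axis=1), 1.0)


class TestForwardContracts:
    def test_latent_is_last_hidden_state_of_configured_width(self, model, tiny_dataset):
        latent, hs = model.encode(tiny_dataset.X[:3])
        assert latent.shape == (3, model.config.latent_dim)
        np.testing.assert_array_equal(latent.data, hs[-1].data)
        assert len(hs) == 24

    def test_default_latent_dim_is_128(self):
        assert BackboneConfig().latent_dim == 128

    def test_encode_rejects_nan(self, model, tiny_dataset):
        X = tiny_dataset.X[:1].copy()
        X[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            model.encode(X)

    def test_decoder_matches_flattened_input_shape(self, model, tiny_dataset):
        X = tiny_dataset.X[:2]
        latent, hs = model.encode(X)
        recon = model.decode(hs)
        C, H = X.shape[1], X.shape[3]
        assert len(recon) == 24 and recon[0].shape == (2, C * H)
        assert model.reconstruction_error(X, recon).data.item() >= 0

    def test_forward_deterministic(self, model, tiny_dataset):
        a = model.classify(tiny_dataset.X[:4], tiny_dataset.covariates[:4],
                           tiny_dataset.subjects[:4])
        b = model.classify(tiny_dataset.X[:4], tiny_dataset.covariates[:4],
                           tiny_dataset.subjects[:4])
        np.testing.assert_array_equal(a, b)

    def test_probabilities_sum_to_one(self, model, tiny_dataset):
        p = model.classify(tiny_dataset.X[:5], tiny_dataset.covariates[:5],
                           tiny_dataset.subjects[:5])
        assert p.shape == (5, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_distinct_heads_generally_disagree(self, model, tiny_dataset):
        subs = tiny_dataset.subject_list
        same_x = tiny_dataset.X[:1]
        same_c = tiny_dataset.covariates[:1]
        p0 = model.classify(same_x, same_c, np.array([subs[0]]))
        p1 = model.classify(same_x, same_c, np.array([subs[1]]))
        assert not np.allclose(p0, p1)

    def test_unknown_subject_raises_cold_start_error(self, model, tiny_dataset):
        with pytest.raises(ColdStartError, match="generic"):
            model.classify(tiny_dataset.X[:1], tiny_dataset.covariates[:1],
                           np.array(["stranger"]))

    def test_generic_head_serves_unknown_subjects(self, model, tiny_dataset):
        p = model.classify(tiny_dataset.X[:1], tiny_dataset.covariates[:1],
                           generic=True)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestTraining:
    def test_history_bookkeeping_and_reproducibility(self, tiny_dataset, small_backbone):
        n, C, T, H = tiny_dataset.X.shape

        def fit():
            m = StressModel(C, H, tiny_dataset.covariates.shape[1],
                            tiny_dataset.subject_list, config=small_backbone, seed=1)
            hist = train_model(m, tiny_dataset, TrainConfig(epochs=3), seed=5)
            return m, hist

        m1, h1 = fit()
        m2, h2 = fit()
        assert len(h1) == 3
        assert [t.ce_personal for t in h1] == [t.ce_personal for t in h2]
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_loss_with_alpha_zero_matches_ce_only_oracle(self, tiny_dataset, small_backbone):
        """With alpha=0 the integrated loss reduces to classification CE,
        recomputed here independently from predicted probabilities."""
        n, C, T, H = tiny_dataset.X.shape
        m = StressModel(C, H, tiny_dataset.covariates.shape[1],
                        tiny_dataset.subject_list, config=small_backbone, seed=2)
        w = LossWeights(alpha=0.0, beta=1.0)
        proba = m.predict_proba(tiny_dataset)
        oracle = -np.mean(np.log(proba[np.arange(len(tiny_dataset)),
                                        tiny_dataset.labels - 1]))
        from stresslearn.model import Trainer

        tr = Trainer(m, tiny_dataset, TrainConfig(epochs=1, loss=w,
                                                  with_generic=False), seed=0)
        ce = tr.eval_personal_ce()
        assert ce == pytest.approx(oracle, rel=1e-9)
        assert integrated_loss(LossTerms(99.0, ce), w) == pytest.approx(oracle)

    def test_overfitting_single_example_reduces_reconstruction(self, tiny_dataset):
        ds = tiny_dataset.subset([0])
        n, C, T, H = tiny_dataset.X.shape
        m = StressModel(C, H, ds.covariates.shape[1], ds.subject_list.copy(),
                        config=BackboneConfig(latent_dim=8, shared_width=8,
                                              head_hidden=4), seed=0)
        cfg = TrainConfig(epochs=12, batch_size=1,
                          loss=LossWeights(alpha=1.0, beta=0.0),
                          with_generic=False)
        hist = train_model(m, ds, cfg, seed=0)
        assert hist[-1].re < hist[0].re

    def test_pooled_head_map_uses_single_head(self, tiny_dataset, small_backbone):
        n, C, T, H = tiny_dataset.X.shape
        m = StressModel(C, H, tiny_dataset.covariates.shape[1],
                        tiny_dataset.subject_list, config=small_backbone, seed=0,
                        head_map={s: POOLED for s in tiny_dataset.subject_list})
        assert set(m.heads) == {POOLED}
        p = m.predict_proba(tiny_dataset)
        assert p.shape == (len(tiny_dataset), 3)


class TestCheckpoint:
    def test_round_trip_reproduces_predictions(self, tiny_dataset, small_backbone,
                                               tmp_path):
        from stresslearn import load_checkpoint, save_checkpoint

        m = StressModel(5, 4, tiny_dataset.covariates.shape[1],
                        tiny_dataset.subject_list, config=small_backbone, seed=3)
        path = tmp_path / "ckpt"
        save_checkpoint(m, str(path))
        m2 = load_checkpoint(str(path))
        np.testing.assert_array_equal(m.predict_proba(tiny_dataset),
                                      m2.predict_proba(tiny_dataset))

    def test_branched_round_trip_keeps_groups(self, tiny_dataset, small_backbone,
                                              tmp_path):
        from stresslearn import BranchedStressModel, load_checkpoint, save_checkpoint

        m = BranchedStressModel(5, 4, tiny_dataset.covariates.shape[1],
                                tiny_dataset.subject_list, n_branches=2,
                                config=small_backbone, seed=3)
        m.branch_logits.data[0, :] = 2.0  # non-trivial selection
        path = tmp_path / "ckpt"
        save_checkpoint(m, str(path))
        m2 = load_checkpoint(str(path))
        assert m2.groups() == m.groups()
        np.testing.assert_array_equal(m.predict_proba(tiny_dataset),
                                      m2.predict_proba(tiny_dataset))
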