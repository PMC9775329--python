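import math

import numpy as np
import pytest

from evcoder.autoencoder import (AutoencoderConfig, ModelFormatError,
                                 TrainedAutoencoder, UntrainedModelError,
                                 bce_loss, finetune, init_network,
                                 pretrain_layerwise, train_autoencoder)


def brute_force_bce(t, r, clamp=1e-7):
    """Independent element-by-element evaluation of the loss formula."""
    total, count = 0.0, 0
    for ti, ri in zip(np.ravel(t), np.ravel(r)):
        ri = min(max(ri, clamp), 1 - clamp)
        total += -(ti * math.log(ri) + (1 - ti) * math.log(1 - ri))
        count += 1
    return total / count


class TestBCELoss:
    def test_half_half_is_ln2(self):
        half = np.full(20, 0.5)
        assert bce_loss(half, half) == pytest.approx(math.log(2), abs=1e-12)

    def test_binary_target_infimum_zero(self):
        t = np.zeros(20)
        t[0] = 1.0
        r = np.clip(t, 1e-7, 1 - 1e-7)
        assert bce_loss(t, r) == pytest.approx(0.0, abs=1e-5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.random(20)
            r = rng.random(20)
            assert bce_loss(t, r) == pytest.approx(brute_force_bce(t, r), abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            bce_loss(np.zeros(20), np.full(19, 0.5))


class TestConfig:
    def test_defaults_follow_recipe(self):
        cfg = AutoencoderConfig()
        assert cfg.layer_sizes == (20, 15, 10, 5, 2)
        assert cfg.learning_rate == 1e-3
        assert cfg.batch_size == 128

    @pytest.mark.parametrize("sizes", [(20, 15, 10, 5, 3), (20, 16, 8, 4, 2)])
    def test_alternate_schemes_accepted(self, sizes):
        assert AutoencoderConfig(layer_sizes=sizes).bottleneck == sizes[-1]

    @pytest.mark.parametrize(
        "sizes", [(20,), (19, 10, 2), (20, 10, 10, 2), (20, 5, 10, 2)]
    )
    def test_invalid_layer_sizes_rejected(self, sizes):
        with pytest.raises(ValueError):
            AutoencoderConfig(layer_sizes=sizes)


class TestInitNetwork:
    def test_same_seed_identical_parameters(self):
        cfg = AutoencoderConfig(seed=9)
        a, b = init_network(cfg), init_network(cfg)
        for la, lb in zip(a.encoder + a.decoder, b.encoder + b.decoder):
            for pa, pb in zip(la.params(), lb.params()):
                np.testing.assert_array_equal(pa, pb)

    def test_parameter_count_closed_form(self):
        sizes = (20, 15, 10, 5, 2)
        model = init_network(AutoencoderConfig(layer_sizes=sizes))
        weights = 2 * sum(a * b for a, b in zip(sizes, sizes[1:]))  # untied
        biases = sum(sizes[1:]) + sum(sizes[:-1])  # encoder + mirrored decoder
        expected = weights + biases
        expected += 2 * sum(sizes[1:])      # encoder batch-norm gamma/beta
        expected += 2 * sum(sizes[1:-1])    # decoder hidden batch-norm
        assert model.parameter_count() == expected

    def test_bottleneck_three(self):
        model = init_network(AutoencoderConfig(layer_sizes=(20, 15, 10, 5, 3)))
        code = model.encode(np.eye(20)[:4], allow_untrained=True)
        assert code.shape == (4, 3)


class TestTraining:
    def test_pretraining_reduces_each_stage_loss(self, small_corpus):
        _, X, _ = small_corpus
        cfg = AutoencoderConfig(seed=1, pretrain_epochs=5, finetune_epochs=1)
        pairs, histories = pretrain_layerwise(X[:500], cfg)
        assert len(pairs) == 4
        for hist in histories:
            assert all(np.isfinite(hist))
            assert hist[-1] <= hist[0]

    def test_codes_stay_in_unit_interval_at_every_depth(self, small_corpus):
        _, X, _ = small_corpus
        cfg = AutoencoderConfig(seed=1, pretrain_epochs=2, finetune_epochs=1)
        pairs, _ = pretrain_layerwise(X[:300], cfg)
        codes = X[:300]
        for enc, _dec in pairs:
            codes = enc.forward(codes, training=False)
            assert ((codes > 0) & (codes < 1)).all()

    def test_finetune_improves_on_assembled_stack(self, small_model):
        hist = small_model.loss_history
        assert all(np.isfinite(hist["finetune"]))
        assert len(hist["finetune"]) == small_model.config.finetune_epochs
        assert hist["final_loss"] <= hist["initial_finetune_loss"]

    def test_training_is_deterministic(self, small_corpus):
        _, X, _ = small_corpus
        cfg = AutoencoderConfig(seed=4, pretrain_epochs=2, finetune_epochs=3)
        a = train_autoencoder(X[:400], cfg)
        b = train_autoencoder(X[:400], cfg)
        assert a.loss_history == b.loss_history
        for la, lb in zip(a.encoder + a.decoder, b.encoder + b.decoder):
            for pa, pb in zip(la.params(), lb.params()):
                np.testing.assert_array_equal(pa, pb)

    def test_weights_are_untied(self, small_model):
        for enc, dec in zip(small_model.encoder, reversed(small_model.decoder)):
            assert not np.allclose(enc.W, dec.W.T)

    def test_empty_data_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pretrain_layerwise(np.empty((0, 20)), AutoencoderConfig())

    def test_two_profile_capacity(self):
        """A 2-unit bottleneck memorizes two distinct profiles almost exactly.

        The BCE lower bound at a target t is t's own elementwise binary
        entropy (attained at r = t); training should come within 10% of it.
        """
        a = np.zeros(20)
        a[:2] = (0.7, 0.3)
        b = np.zeros(20)
        b[:4] = (0.4, 0.3, 0.2, 0.1)
        X = np.repeat(np.stack([a, b]), 100, axis=0)
        cfg = AutoencoderConfig(seed=2, batch_size=32, pretrain_epochs=20,
                                finetune_epochs=300)
        model = train_autoencoder(X, cfg)
        bound = bce_loss(X, np.clip(X, 1e-7, 1 - 1e-7))
        achieved = bce_loss(X, model.reconstruct(X))
        assert achieved <= 1.10 * bound


class TestInference:
    def test_untrained_model_refuses_inference(self):
        model = init_network(AutoencoderConfig())
        with pytest.raises(UntrainedModelError):
            model.encode(np.eye(20)[:1])

    def test_encode_deterministic_and_batch_independent(self, small_model, small_corpus):
        _, X, _ = small_corpus
        full = small_model.encode(X[:64])
        np.testing.assert_array_equal(full, small_model.encode(X[:64]))
        # running statistics, not batch statistics: a batch of one encodes
        # the same as the corresponding row of a larger batch (up to BLAS
        # kernel round-off)
        single = small_model.encode(X[5])
        np.testing.assert_allclose(single[0], full[5], rtol=1e-12, atol=0)

    def test_outputs_strictly_inside_unit_interval(self, small_model, small_corpus):
        _, X, _ = small_corpus
        code = small_model.encode(X[:200])
        recon = small_model.reconstruct(X[:200])
        assert code.shape == (200, 2)
        assert ((code > 0) & (code < 1)).all()
        assert ((recon > 0) & (recon < 1)).all()

    def test_trained_beats_untrained_on_held_out(self, small_model, small_corpus):
        _, X, _ = small_corpus
        held = X[1500:]
        untrained = init_network(small_model.config)
        assert bce_loss(held, small_model.reconstruct(held)) < \
            bce_loss(held, untrained.reconstruct(held, allow_untrained=True))


class TestPersistence:
    def test_round_trip_preserves_encoding(self, tmp_path, small_model, small_corpus):
        _, X, _ = small_corpus
        path = tmp_path / "model.json"
        small_model.save(path)
        loaded = TrainedAutoencoder.load(path)
        np.testing.assert_array_equal(
            small_model.encode(X[:50]), loaded.encode(X[:50])
        )
        assert loaded.config == small_model.config

    def test_corrupted_file_clear_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelFormatError, match="not a valid model file"):
            TrainedAutoencoder.load(path)

    def test_version_mismatch(self, tmp_path, small_model):
        path = tmp_path / "model.json"
        small_model.save(path)
        text = path.read_text().replace("evcoder-model-1", "evcoder-model-99")
        path.write_text(text)
        with pytest.raises(ModelFormatError, match="unsupported model format"):
            TrainedAutoencoder.load(path)
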