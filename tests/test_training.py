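"""Adversarial training: losses, step isolation, reproducibility, dynamics."""

import hashlib

import numpy as np
import pytest

from lsproj import (ImageGenConfig, NetworkSpec, LSPModel, TrainingConfig,
                    build_decoder, build_discriminator, build_encoder,
                    fit_latent_statistics, generate_images, privacy_loss,
                    reconstruction_loss, train_lsp)
from lsproj import nn
from lsproj.training import autoencoder_step, build_aux_head, discriminator_step


class TestReconstructionLoss:
    def test_identity_is_zero(self, rng):
        x = rng.random((4, 8, 8))
        assert reconstruction_loss(x, x) == 0.0

    def test_uniform_offset_closed_form(self, rng):
        x = rng.random((4, 8, 8))
        assert reconstruction_loss(x, x + 0.1) == pytest.approx(0.01, rel=1e-9)

    def test_matches_elementwise_brute_force(self, rng):
        x, y = rng.random((3, 5, 5)), rng.random((3, 5, 5))
        brute = sum((float(x[i, j, k]) - float(y[i, j, k])) ** 2
                    for i in range(3) for j in range(5) for k in range(5)) / 75
        assert reconstruction_loss(x, y) == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss(rng.random(4), rng.random(5))


class TestPrivacyLoss:
    def test_confident_correct_prediction_near_zero(self):
        assert privacy_loss(np.array([1.0, 0.0]), np.array([1, 0])) <= 1e-6

    def test_uniform_binary_is_ln2(self):
        p = np.full(10, 0.5)
        s = np.array([0, 1] * 5)
        assert privacy_loss(p, s) == pytest.approx(np.log(2), rel=1e-9)

    def test_matches_per_sample_brute_force(self, rng):
        p = rng.random(20)
        s = rng.integers(0, 2, 20)
        brute = -np.mean([np.log((p[i] if s[i] else 1 - p[i]) + 1e-12)
                          for i in range(20)])
        assert privacy_loss(p, s) == pytest.approx(brute, rel=1e-9)

    def test_categorical_rows(self, rng):
        p = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
        s = np.array([0, 1])
        brute = -(np.log(0.7 + 1e-12) + np.log(0.8 + 1e-12)) / 2
        assert privacy_loss(p, s) == pytest.approx(brute, rel=1e-9)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            privacy_loss(np.array([1.2]), np.array([1]))


def _params_digest(*nets):
    h = hashlib.sha256()
    for net in nets:
        for p in net.params():
            h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()


def _tiny_setup(seed=0, gamma=1.0):
    data = generate_images(ImageGenConfig(n_samples=64, image_size=16, seed=seed))
    spec = NetworkSpec("image", (16, 16), latent_dim=16, d_s=2)
    model = LSPModel(build_encoder(spec, seed), build_decoder(spec, seed + 1),
                     spec, seed=seed)
    disc = build_discriminator(spec, seed + 2)
    config = TrainingConfig(gamma=gamma, epochs=1, batch_size=32, seed=seed)
    return data, model, disc, config


class TestStepIsolation:
    """The adversarial game never lets one player update the other."""

    def test_discriminator_step_leaves_autoencoder_untouched(self):
        data, model, disc, config = _tiny_setup()
        opt = nn.Adam(disc.net.params())
        before = _params_digest(model.encoder, model.decoder)
        disc_before = _params_digest(disc.net)
        discriminator_step(model, disc, data.X[:32], data.s[:32], opt)
        assert _params_digest(model.encoder, model.decoder) == before
        assert _params_digest(disc.net) != disc_before

    def test_autoencoder_step_leaves_discriminator_untouched(self):
        data, model, disc, config = _tiny_setup()
        aux = build_aux_head(model.spec, 9)
        opt = nn.Adam(model.encoder.params() + model.decoder.params() + aux.params())
        disc_before = _params_digest(disc.net)
        ae_before = _params_digest(model.encoder, model.decoder)
        autoencoder_step(model, disc, aux, data.X[:32], data.s[:32], opt, config)
        assert _params_digest(disc.net) == disc_before
        assert _params_digest(model.encoder, model.decoder) != ae_before


class TestDegenerateLimit:
    def test_gamma0_lambda0_equals_plain_autoencoder_step(self):
        """With both privacy terms off, one training step is bit-identical
        to a hand-rolled reconstruction-only Adam step."""
        data, model, disc, _ = _tiny_setup()
        config = TrainingConfig(gamma=0.0, lambda_s=0.0, epochs=1,
                                batch_size=32, grad_clip=0.0, seed=0)
        aux = build_aux_head(model.spec, 9)
        opt = nn.Adam(model.encoder.params() + model.decoder.params() + aux.params())
        x = data.X[:32]
        autoencoder_step(model, disc, aux, x, data.s[:32], opt, config)

        # independent reconstruction-only step on a fresh identical model
        data2, model2, _, _ = _tiny_setup()
        xi = model2._to_internal(x)
        z = model2.encoder.forward(xi, train=True)
        xd = model2.decoder.forward(z, train=True)
        diff = (xd + 1) / 2 - (xi + 1) / 2
        opt2 = nn.Adam(model2.encoder.params() + model2.decoder.params())
        for g in model2.encoder.grads() + model2.decoder.grads():
            g[...] = 0.0
        gz = model2.decoder.backward(diff * (2.0 / diff.size) * 0.5)
        model2.encoder.backward(gz)
        opt2.step(model2.encoder.grads() + model2.decoder.grads())

        for a, b in zip(model.encoder.params() + model.decoder.params(),
                        model2.encoder.params() + model2.decoder.params()):
            assert np.array_equal(a, b)


class TestTrainingLoop:
    def test_identical_seed_identical_history(self):
        runs = []
        for _ in range(2):
            data, model, disc, config = _tiny_setup(seed=4, gamma=0.5)
            config.epochs = 2
            _, _, hist = train_lsp(model, disc, data, config)
            runs.append(hist)
        assert runs[0].reconstruction == runs[1].reconstruction
        assert runs[0].discriminator == runs[1].discriminator
        assert runs[0].final_reconstruction_error == runs[1].final_reconstruction_error

    def test_reconstruction_loss_declines(self, trained_autoencoder):
        _, _, hist = trained_autoencoder
        assert hist.reconstruction[-1] < hist.reconstruction[0]
        assert all(np.isfinite(v) for v in hist.reconstruction)

    def test_history_has_one_record_per_epoch(self, trained_autoencoder):
        _, _, hist = trained_autoencoder
        assert hist.n_epochs() == 6
        assert len(hist.to_frame()) == 6

    def test_modality_mismatch_rejected(self, small_table):
        _, model, disc, config = _tiny_setup()
        with pytest.raises(ValueError, match="modality"):
            train_lsp(model, disc, small_table, config)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(gamma=-1.0).validate()


class TestLatentStatistics:
    def test_mean_matches_brute_force(self, trained_autoencoder, small_images):
        model, _, _ = trained_autoencoder
        zs = np.concatenate([model.encode(small_images.X[i:i + 256]).z_s
                             for i in range(0, len(small_images), 256)])
        assert np.allclose(model.zs_mean, zs.mean(axis=0), atol=1e-6)

    def test_constant_dataset_mean_is_the_single_code(self):
        data, model, disc, config = _tiny_setup()
        const = data.subset(np.zeros(8, dtype=int))
        fit_latent_statistics(model, const)
        single = model.encode(const.X[:1]).z_s[0]
        assert np.allclose(model.zs_mean, single, atol=1e-6)

    def test_reservoir_respects_cap(self, small_images):
        _, model, disc, config = _tiny_setup()
        spec16 = model.spec
        fit_latent_statistics(model, small_images, cap=100)
        assert len(model.zs_bank) == 100

    def test_resample_mode_is_seeded(self, trained_autoencoder, small_images):
        model, _, _ = trained_autoencoder
        x = small_images.X[:5]
        a = model.obfuscate(x, "resample", seed=3)
        b = model.obfuscate(x, "resample", seed=3)
        assert np.array_equal(a, b)
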