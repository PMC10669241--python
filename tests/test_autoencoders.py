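"""SCAE/VCAE construction, reparameterization, losses, training loop."""

import numpy as np
import pytest
from scipy import integrate

from taxonembed.autoencoders import (
    CAEConfig,
    LatentGaussian,
    ShapeError,
    build_scae,
    build_vcae,
    encode_features,
    gaussian_kl,
    reparameterize,
    train_autoencoder,
    vcae_loss,
    vcae_loss_latent_grads,
)

TINY = CAEConfig(filters_per_layer=(6, 4, 3), kernel_size=5, bottleneck_dim=4,
                 batch_size=8, max_epochs=5, patience_epochs=3,
                 learning_rate=0.005, seed=0)


def tiny_data(rng, n=40, length=32, channels=2):
    """Low-rank data: three smooth temporal patterns with random weights.

    Smoothness keeps the patterns within reach of a short-kernel
    convolutional code."""
    t = np.linspace(0, 2 * np.pi, length)
    phases = rng.uniform(0, 2 * np.pi, size=(3, channels))
    freqs = np.array([1.0, 2.0, 3.0])
    basis = np.stack([np.sin(f * t[:, None] + ph) for f, ph in zip(freqs, phases)])
    w = rng.normal(size=(n, 3))
    return np.tensordot(w, basis, axes=1) + rng.normal(0, 0.05, (n, length, channels))


class TestConstruction:
    def test_bottleneck_spatial_arithmetic(self):
        cfg = CAEConfig(bottleneck_dim=8)
        model = build_scae(cfg, (3000, 32))
        assert model.bottleneck_spatial == 375

    def test_default_filter_counts(self):
        cfg = CAEConfig()
        assert cfg.filters_per_layer == (128, 64, 32)
        assert cfg.kernel_size == 22
        assert cfg.batch_size == 100
        assert cfg.learning_rate == 0.001

    def test_indivisible_length_rejected_with_minimum(self):
        with pytest.raises(ShapeError, match="multiple of pool"):
            build_scae(TINY, (30, 2))

    def test_reconstruction_shape_matches_input(self, rng):
        model = build_scae(TINY, (32, 2))
        x = rng.normal(size=(4, 32, 2))
        assert model.reconstruct(x).shape == x.shape

    def test_vcae_heads_emit_two_bottleneck_vectors(self, rng):
        model = build_vcae(TINY, (32, 2))
        lat = model.latent(rng.normal(size=(3, 32, 2)))
        assert lat.mu.shape == (3, 4) and lat.log_var.shape == (3, 4)

    def test_trunk_parameter_counts_match_across_architectures(self):
        scae = build_scae(TINY, (32, 2))
        vcae = build_vcae(TINY, (32, 2))
        assert scae.trunk_parameter_count() == vcae.trunk_parameter_count()

    def test_increasing_filters_rejected(self):
        with pytest.raises(ValueError):
            CAEConfig(filters_per_layer=(8, 16, 32))


class TestReparameterize:
    def test_zero_noise_returns_mu(self):
        lat = LatentGaussian(np.array([1.0, -2.0]), np.array([0.3, 0.3]))
        assert np.array_equal(reparameterize(lat, np.zeros(2)), lat.mu)

    def test_unit_variance_adds_noise_directly(self):
        lat = LatentGaussian(np.array([1.0, 2.0]), np.zeros(2))
        e = np.array([0.5, -0.5])
        assert np.allclose(reparameterize(lat, e), [1.5, 1.5])

    def test_monte_carlo_moments(self, rng):
        mu = np.array([0.7, -1.2, 2.0])
        log_var = np.array([0.4, -0.8, 0.1])
        lat = LatentGaussian(mu, log_var)
        n = 100_000
        eps = rng.standard_normal((n, 3))
        z = lat.mu + np.exp(0.5 * lat.log_var) * eps
        sigma = np.exp(0.5 * log_var)
        assert (np.abs(z.mean(axis=0) - mu) < 4 * sigma / np.sqrt(n)).all()
        assert (np.abs(z.var(axis=0) / np.exp(log_var) - 1) < 0.05).all()

    def test_shape_mismatch_rejected(self):
        lat = LatentGaussian(np.zeros(3), np.zeros(3))
        with pytest.raises(ShapeError):
            reparameterize(lat, np.zeros(4))


def kl_quadrature(mu, log_var):
    """Numerical KL(N(mu, s^2) || N(0,1)) integrated per dimension.

    The integrand uses analytic log-densities so tail underflow cannot
    produce log(0)."""
    total = 0.0
    for m, lv in zip(mu, log_var):
        s = np.exp(0.5 * lv)

        def f(x, m=m, s=s):
            logp = -0.5 * ((x - m) / s) ** 2 - np.log(s)
            logq = -0.5 * x**2
            return np.exp(logp - 0.5 * np.log(2 * np.pi)) * (logp - logq)

        lo, hi = min(m - 10 * s, -10.0), max(m + 10 * s, 10.0)
        val, _ = integrate.quad(f, lo, hi, limit=400)
        total += val
    return total


class TestVCAELoss:
    def test_prior_match_gives_zero_kl(self):
        assert gaussian_kl(np.zeros(4), np.zeros(4)) == 0.0

    def test_kl_nonnegative(self, rng):
        for _ in range(50):
            mu = rng.normal(size=5)
            lv = rng.normal(size=5)
            assert gaussian_kl(mu, lv) >= 0.0

    def test_half_for_unit_mean_shift(self):
        assert np.isclose(gaussian_kl(np.array([1.0, 0.0]), np.zeros(2)), 0.5)
        assert np.isclose(kl_quadrature([1.0, 0.0], [0.0, 0.0]), 0.5, atol=1e-8)

    def test_closed_form_matches_quadrature(self, rng):
        for _ in range(5):
            mu = rng.normal(size=3)
            lv = rng.normal(scale=0.8, size=3)
            assert np.isclose(gaussian_kl(mu, lv), kl_quadrature(mu, lv), atol=1e-6)

    def test_total_is_mse_plus_beta_kl(self, rng):
        x = rng.normal(size=(2, 8, 1))
        x_hat = rng.normal(size=(2, 8, 1))
        lat = LatentGaussian(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        total, recon, kl = vcae_loss(x, x_hat, lat, beta=0.5)
        assert np.isclose(recon, np.mean((x - x_hat) ** 2))
        assert np.isclose(total, recon + 0.5 * kl)

    def test_nonfinite_loss_aborts(self):
        lat = LatentGaussian(np.array([[np.inf]]), np.array([[0.0]]))
        with pytest.raises(FloatingPointError):
            vcae_loss(np.zeros((1, 2, 1)), np.zeros((1, 2, 1)), lat)

    def test_latent_gradients_match_finite_differences(self, rng):
        x = rng.normal(size=(4, 6, 1))
        x_hat = rng.normal(size=(4, 6, 1))
        mu = rng.normal(size=(4, 3))
        lv = rng.normal(scale=0.5, size=(4, 3))
        dmu, dlv = vcae_loss_latent_grads(LatentGaussian(mu, lv))
        h = 1e-6
        for arr, grad in ((mu, dmu), (lv, dlv)):
            for idx in [(0, 0), (1, 2), (3, 1)]:
                old = arr[idx]
                arr[idx] = old + h
                up, *_ = vcae_loss(x, x_hat, LatentGaussian(mu, lv))
                arr[idx] = old - h
                dn, *_ = vcae_loss(x, x_hat, LatentGaussian(mu, lv))
                arr[idx] = old
                num = (up - dn) / (2 * h)
                assert abs(num - grad[idx]) <= 1e-4 * max(1.0, abs(num))


class TestTraining:
    def test_runs_to_max_epochs_when_improving(self, rng):
        model = build_scae(TINY, (32, 2))
        data = tiny_data(rng)
        model, hist = train_autoencoder(model, data[:30], data[30:], TINY)
        # improving losses: early stopping never triggers before max_epochs
        assert len(hist.frame) <= TINY.max_epochs
        if not hist.stopped_early:
            assert len(hist.frame) == TINY.max_epochs

    def test_frozen_validation_stops_after_patience(self, rng):
        cfg = CAEConfig(filters_per_layer=(4, 3, 2), kernel_size=3, bottleneck_dim=2,
                        batch_size=8, max_epochs=30, patience_epochs=3,
                        learning_rate=0.0, seed=1)
        model = build_scae(cfg, (16, 1))
        data = rng.normal(size=(20, 16, 1))
        model, hist = train_autoencoder(model, data[:15], data[15:], cfg)
        assert hist.stopped_early
        assert len(hist.frame) == hist.best_epoch + cfg.patience_epochs

    def test_training_reduces_reconstruction_error(self, rng):
        model = build_scae(TINY, (32, 2))
        data = tiny_data(rng, n=50)
        model, hist = train_autoencoder(model, data[:40], data[40:], TINY)
        assert hist.frame["train_loss"].iloc[-1] < hist.frame["train_loss"].iloc[0]

    def test_trained_scae_beats_random_weights_5x(self, rng):
        cfg = CAEConfig(filters_per_layer=(8, 6, 4), kernel_size=5, bottleneck_dim=6,
                        batch_size=8, max_epochs=250, patience_epochs=250,
                        learning_rate=0.01, seed=2)
        data = tiny_data(rng, n=60) * 3.0
        random_model = build_scae(cfg, (32, 2))
        base = random_model.validation_loss(data[48:])
        model = build_scae(cfg, (32, 2))
        model, _ = train_autoencoder(model, data[:48], data[48:], cfg)
        trained = model.validation_loss(data[48:])
        assert trained * 5 <= base

    def test_vcae_total_loss_decreases_early(self, rng):
        passes = 0
        for seed in range(5):
            cfg = CAEConfig(filters_per_layer=(6, 4, 3), kernel_size=5,
                            bottleneck_dim=4, batch_size=8, max_epochs=3,
                            patience_epochs=3, learning_rate=0.005, seed=seed)
            model = build_vcae(cfg, (32, 2))
            data = tiny_data(np.random.default_rng(seed), n=40)
            model, hist = train_autoencoder(model, data[:32], data[32:], cfg)
            if hist.frame["train_loss"].iloc[-1] < hist.frame["train_loss"].iloc[0]:
                passes += 1
        assert passes >= 4

    def test_empty_split_rejected(self, rng):
        model = build_scae(TINY, (32, 2))
        with pytest.raises(ValueError):
            train_autoencoder(model, np.empty((0, 32, 2)), rng.normal(size=(2, 32, 2)), TINY)


class TestEncodeFeatures:
    def test_shape_and_determinism(self, rng):
        model = build_scae(TINY, (32, 2))
        data = tiny_data(rng, n=20)
        model, _ = train_autoencoder(model, data[:16], data[16:], TINY)
        f1 = encode_features(model, data)
        f2 = encode_features(model, data)
        assert f1.shape == (20, TINY.bottleneck_dim)
        assert np.array_equal(f1, f2)

    def test_identical_inputs_identical_rows(self, rng):
        model = build_scae(TINY, (32, 2))
        data = tiny_data(rng, n=10)
        model, _ = train_autoencoder(model, data[:8], data[8:], TINY)
        double = np.vstack([data[:1], data[:1]])
        feats = encode_features(model, double)
        assert np.array_equal(feats[0], feats[1])

    def test_vcae_features_ignore_sampling(self, rng):
        model = build_vcae(TINY, (32, 2))
        data = tiny_data(rng, n=20)
        model, _ = train_autoencoder(model, data[:16], data[16:], TINY)
        assert np.array_equal(encode_features(model, data), encode_features(model, data))
        assert encode_features(model, data).shape == (20, TINY.bottleneck_dim)

    def test_untrained_model_rejected(self, rng):
        model = build_scae(TINY, (32, 2))
        with pytest.raises(RuntimeError):
            encode_features(model, tiny_data(rng, n=4))
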