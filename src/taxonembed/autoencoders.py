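"""Stacked (SCAE) and variational (VCAE) convolutional autoencoders.

Both share the same convolutional trunk: three conv + ReLU + max-pool
blocks along the segment/token axis (embedding dimensions are channels),
a flatten, and a fully connected bottleneck.  The decoder mirrors the
encoder with stride-2 transposed convolutions.  The VCAE bottleneck
emits a diagonal Gaussian (mu, log-variance) sampled with the
reparameterization trick; at inference its features are the mu vector,
so downstream behavior is deterministic.

Training minimizes mean squared reconstruction error (plus beta-weighted
KL against the standard normal prior for the VCAE) with Adam and early
stopping on validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from taxonembed.nn import (
    Adam,
    Conv1D,
    ConvTranspose1D,
    Dense,
    Flatten,
    MaxPool1D,
    ReLU,
    Reshape,
    Sequential,
    get_weights,
    set_weights,
)


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class CAEConfig:
    """Hyperparameters shared by both autoencoder architectures.

    Defaults follow the full-scale configuration (filters 128/64/32,
    kernel 22, Adam at 1e-3, batch 100, patience 10); tests and the
    desk-scale pipeline shrink them.
    """

    filters_per_layer: tuple[int, ...] = (128, 64, 32)
    kernel_size: int = 22
    pool_size: int = 2
    bottleneck_dim: int = 32
    learning_rate: float = 0.001
    batch_size: int = 100
    max_epochs: int = 10
    patience_epochs: int = 10
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.filters_per_layer):
            raise ValueError("filter counts must be positive")
        if any(a < b for a, b in zip(self.filters_per_layer, self.filters_per_layer[1:])):
            raise ValueError("filters must be non-increasing across encoder layers")
        if min(self.kernel_size, self.pool_size, self.bottleneck_dim,
               self.batch_size, self.max_epochs, self.patience_epochs) <= 0:
            raise ValueError("all size/epoch parameters must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")


@dataclass(frozen=True)
class LatentGaussian:
    """Diagonal-Gaussian bottleneck parameters (mean and log-variance)."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        if np.shape(self.mu) != np.shape(self.log_var):
            raise ShapeError("mu and log_var shapes differ")


def _check_spatial(length: int, pool: int, n_layers: int) -> int:
    div = pool**n_layers
    if length % div or length // div < 1:
        raise ShapeError(
            f"input length {length} must be a positive multiple of pool^layers = {div}; "
            f"minimum valid length is {div}"
        )
    return length // div


class _ConvAutoencoderBase:
    """Shared trunk/decoder construction and minibatch training loop."""

    def __init__(self, config: CAEConfig, input_shape: tuple[int, int]):
        self.config = config
        self.length, self.channels = input_shape
        n_layers = len(config.filters_per_layer)
        self.bottleneck_spatial = _check_spatial(self.length, config.pool_size, n_layers)
        if config.pool_size != 2:
            raise ShapeError("decoder upsampling is stride-2; pool_size must be 2")
        self.rng = np.random.default_rng(config.seed)
        layers: list = []
        c_prev = self.channels
        for f in config.filters_per_layer:
            layers += [Conv1D(c_prev, f, config.kernel_size, self.rng), ReLU(),
                       MaxPool1D(config.pool_size)]
            c_prev = f
        layers.append(Flatten())
        self.encoder_trunk = Sequential(layers)
        self.flat_dim = self.bottleneck_spatial * config.filters_per_layer[-1]
        self._build_heads()
        self.decoder = self._build_decoder()
        self.fitted = False

    def _build_decoder(self) -> Sequential:
        cfg = self.config
        filters = cfg.filters_per_layer
        layers: list = [Dense(cfg.bottleneck_dim, self.flat_dim, self.rng), ReLU(),
                        Reshape((self.bottleneck_spatial, filters[-1]))]
        chans = [filters[-1]] + list(reversed(filters[:-1])) + [filters[0]]
        for c_in, c_out in zip(chans, chans[1:]):
            layers += [ConvTranspose1D(c_in, c_out, self.rng), ReLU()]
        layers.append(Conv1D(chans[-1], self.channels, cfg.kernel_size, self.rng))
        return Sequential(layers)

    def trunk_parameter_count(self) -> int:
        return sum(p.value.size for p in self.encoder_trunk.params())

    def params(self):
        raise NotImplementedError

    def loss_forward_backward(self, x: np.ndarray, train_rng: np.random.Generator):
        """Return (total, recon, kl) and accumulate parameter gradients."""
        raise NotImplementedError

    def encode(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def validation_loss(self, x: np.ndarray) -> float:
        raise NotImplementedError


class StackedConvAutoencoder(_ConvAutoencoderBase):
    """SCAE: deterministic fully connected bottleneck."""

    arch = "scae"

    def _build_heads(self) -> None:
        self.bottleneck = Dense(self.flat_dim, self.config.bottleneck_dim, self.rng)

    def params(self):
        return (self.encoder_trunk.params() + self.bottleneck.params()
                + self.decoder.params())

    def encode(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("autoencoder not trained; call train_autoencoder first")
        return self.bottleneck.forward(self.encoder_trunk.forward(np.asarray(x, float)))

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        h = self.bottleneck.forward(self.encoder_trunk.forward(np.asarray(x, float)))
        return self.decoder.forward(h)

    def loss_forward_backward(self, x, train_rng):
        h = self.bottleneck.forward(self.encoder_trunk.forward(x))
        x_hat = self.decoder.forward(h)
        diff = x_hat - x
        recon = float(np.mean(diff**2))
        dxhat = 2.0 * diff / diff.size
        dh = self.decoder.backward(dxhat)
        self.encoder_trunk.backward(self.bottleneck.backward(dh))
        return recon, recon, 0.0

    def validation_loss(self, x):
        diff = self.reconstruct(x) - x
        return float(np.mean(diff**2))


class VariationalConvAutoencoder(_ConvAutoencoderBase):
    """VCAE: the bottleneck parameterizes a diagonal Gaussian."""

    arch = "vcae"

    def _build_heads(self) -> None:
        self.mu_head = Dense(self.flat_dim, self.config.bottleneck_dim, self.rng)
        self.logvar_head = Dense(self.flat_dim, self.config.bottleneck_dim, self.rng)
        # start from a near-deterministic posterior: with log-variance around
        # -6 the sampling noise (std ~ 0.05) does not drown the decoder signal
        # early in training; the KL term can still widen the posterior later
        self.logvar_head.W.value *= 0.1
        self.logvar_head.b.value[...] = -6.0

    def params(self):
        return (self.encoder_trunk.params() + self.mu_head.params()
                + self.logvar_head.params() + self.decoder.params())

    def latent(self, x: np.ndarray) -> LatentGaussian:
        h = self.encoder_trunk.forward(np.asarray(x, float))
        return LatentGaussian(self.mu_head.forward(h), self.logvar_head.forward(h))

    def encode(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("autoencoder not trained; call train_autoencoder first")
        return self.latent(x).mu

    def encode_with_variance(self, x: np.ndarray) -> np.ndarray:
        lat = self.latent(x)
        return np.concatenate([lat.mu, np.exp(lat.log_var)], axis=1)

    def reconstruct(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        lat = self.latent(x)
        z = lat.mu if eps is None else reparameterize(lat, eps)
        return self.decoder.forward(z)

    def loss_forward_backward(self, x, train_rng):
        h = self.encoder_trunk.forward(x)
        mu = self.mu_head.forward(h)
        log_var = self.logvar_head.forward(h)
        eps = train_rng.standard_normal(mu.shape)
        std = np.exp(0.5 * log_var)
        z = mu + std * eps
        x_hat = self.decoder.forward(z)
        n = x.shape[0]
        diff = x_hat - x
        recon = float(np.mean(diff**2))
        kl = float(-0.5 * np.sum(1.0 + log_var - mu**2 - np.exp(log_var)) / n)
        beta = self.config.beta
        dz = self.decoder.backward(2.0 * diff / diff.size)
        dmu = dz + beta * mu / n
        dlogvar = dz * (0.5 * std * eps) + beta * 0.5 * (np.exp(log_var) - 1.0) / n
        dh = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        self.encoder_trunk.backward(dh)
        return recon + beta * kl, recon, kl

    def validation_loss(self, x):
        lat = self.latent(x)
        x_hat = self.decoder.forward(lat.mu)
        total, _, _ = vcae_loss(x, x_hat, lat, beta=self.config.beta)
        return total


def build_scae(config: CAEConfig, input_shape: tuple[int, int]) -> StackedConvAutoencoder:
    return StackedConvAutoencoder(config, input_shape)


def build_vcae(config: CAEConfig, input_shape: tuple[int, int]) -> VariationalConvAutoencoder:
    return VariationalConvAutoencoder(config, input_shape)


def reparameterize(latent: LatentGaussian, eps: np.ndarray) -> np.ndarray:
    """z = mu + exp(log_var / 2) * eps, elementwise."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape != np.shape(latent.mu):
        raise ShapeError(f"eps shape {eps.shape} != mu shape {np.shape(latent.mu)}")
    return latent.mu + np.exp(0.5 * latent.log_var) * eps


def gaussian_kl(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL( N(mu, diag exp(log_var)) || N(0, I) ), summed over dimensions.

    For batched input the batch mean is returned.
    """
    mu = np.atleast_2d(np.asarray(mu, float))
    log_var = np.atleast_2d(np.asarray(log_var, float))
    per_sample = -0.5 * np.sum(1.0 + log_var - mu**2 - np.exp(log_var), axis=-1)
    return float(per_sample.mean())


def vcae_loss(x: np.ndarray, x_hat: np.ndarray, latent: LatentGaussian,
              beta: float = 1.0) -> tuple[float, float, float]:
    """Total = reconstruction MSE + beta * KL(latent || standard normal)."""
    x = np.asarray(x, float)
    x_hat = np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ShapeError("x and x_hat shapes differ")
    recon = float(np.mean((x - x_hat) ** 2))
    kl = gaussian_kl(latent.mu, latent.log_var)
    total = recon + beta * kl
    if not np.isfinite(total):
        raise FloatingPointError(
            f"non-finite loss: recon={recon}, kl={kl}; aborting training"
        )
    return total, recon, kl


def vcae_loss_latent_grads(latent: LatentGaussian) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the KL term of :func:`vcae_loss` w.r.t. mu and log_var.

    With KL batch-averaged over n samples: d/dmu = mu / n,
    d/dlog_var = (exp(log_var) - 1) / (2 n).
    """
    mu = np.atleast_2d(np.asarray(latent.mu, float))
    log_var = np.atleast_2d(np.asarray(latent.log_var, float))
    n = mu.shape[0]
    dmu = (mu / n).reshape(np.shape(latent.mu))
    dlv = ((np.exp(log_var) - 1.0) / (2.0 * n)).reshape(np.shape(latent.log_var))
    return dmu, dlv


@dataclass
class TrainingHistory:
    """Per-epoch losses and the early-stopping outcome of one fit."""

    frame: pd.DataFrame
    best_epoch: int
    stopped_early: bool

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)


def train_autoencoder(model: _ConvAutoencoderBase, train: np.ndarray,
                      validation: np.ndarray, config: CAEConfig | None = None):
    """Minibatch-Adam training with patience-based early stopping.

    Stops once the validation loss has not improved for
    ``patience_epochs`` consecutive epochs and restores the
    best-validation weights.  Returns ``(model, TrainingHistory)``.
    """
    cfg = config or model.config
    train = np.asarray(train, float)
    validation = np.asarray(validation, float)
    if train.shape[0] == 0 or validation.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    best_val = np.inf
    best_weights = get_weights_of(model)
    best_epoch = 0
    since_best = 0
    rows = []
    stopped = False
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(train.shape[0])
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = train[order[start : start + cfg.batch_size]]
            opt.zero_grad()
            total, _, _ = model.loss_forward_backward(batch, rng)
            if not np.isfinite(total):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(total)
            opt.step()
        model.fitted = True
        val = model.validation_loss(validation)
        if not np.isfinite(val):
            raise FloatingPointError(f"validation loss NaN at epoch {epoch}")
        rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                     "val_loss": val})
        if val < best_val:
            best_val = val
            best_weights = get_weights_of(model)
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience_epochs:
                stopped = True
                break
    set_weights_of(model, best_weights)
    model.fitted = True
    return model, TrainingHistory(pd.DataFrame(rows), best_epoch, stopped)


def get_weights_of(model: _ConvAutoencoderBase) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def set_weights_of(model: _ConvAutoencoderBase, weights: list[np.ndarray]) -> None:
    for p, w in zip(model.params(), weights):
        p.value[...] = w


def encode_features(model: _ConvAutoencoderBase, data: np.ndarray) -> np.ndarray:
    """Bottleneck features, row order preserved (VCAE: the mu vector)."""
    return model.encode(np.asarray(data, float))
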