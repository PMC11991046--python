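"""Convolutional autoencoder and variational autoencoder generators.

One model is trained per activity class (ADL, FALL); synthetic windows of
a class come only from that class's model.

Autoencoder (valid convolutions, so the encoder shortens the signal):

====================  ============
layer                 output shape
====================  ============
Conv1d(64, 3)         (64, 98)
MaxPool1d(2)          (64, 49)
Conv1d(128, 3)        (128, 47)
MaxPool1d(2)          (128, 23)
Conv1d(256, 3)        (256, 21)
MaxPool1d(2)          (256, 10)
Upsample(21)          (256, 21)
ConvTranspose(128,3)  (128, 23)
Upsample(47)          (128, 47)
ConvTranspose(64,3)   (64, 49)
Upsample(98)          (64, 98)
ConvTranspose(6,3)    (6, 100)
====================  ============

A plain autoencoder has no sampling mechanism, so generation perturbs the
latent code of a randomly chosen real window with Gaussian jitter scaled
by the per-dimension latent standard deviation before decoding.

VAE (length-preserving convolutions; kernels 5,5,3,3 down and 3,3,5,5 up):
encoder ends in a MaxPool to (64, 50); two parallel linear maps on the
time axis produce mean and log-variance of a (64, 128) latent; the
decoder maps back through Linear(50), Upsample(100) and four
convolutions.  Training maximizes the evidence lower bound: MSE
reconstruction plus beta * KL(N(mu, sigma^2) || N(0, 1)) with the closed
form KL = -0.5 * sum(1 + log sigma^2 - mu^2 - sigma^2).  New windows are
decoded from prior draws z ~ N(0, I).
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..config import TrainHyper
from ..data import LABEL_ADL, LABEL_FALL, WindowDataset
from . import BaseAugmenter

#: expected activation shapes, audited by tests
AE_ENCODER_SHAPES = [(64, 98), (64, 49), (128, 47), (128, 23), (256, 21), (256, 10)]
AE_DECODER_SHAPES = [(256, 21), (128, 23), (128, 47), (64, 49), (64, 98), (6, 100)]
VAE_ENCODER_SHAPES = [(64, 100), (64, 100), (64, 100), (64, 100), (64, 50)]
VAE_BOTTLENECK_SHAPE = (64, 128)
VAE_DECODER_SHAPES = [(64, 50), (64, 100), (64, 100), (64, 100), (64, 100), (6, 100)]


class Autoencoder(nn.Module):
    """Valid-convolution 1-D autoencoder for 6 x 100 windows."""

    def __init__(self, rng: np.random.Generator):
        self.enc_layers = [
            nn.Conv1d(6, 64, 3, rng=rng), nn.MaxPool1d(2),
            nn.Conv1d(64, 128, 3, rng=rng), nn.MaxPool1d(2),
            nn.Conv1d(128, 256, 3, rng=rng), nn.MaxPool1d(2),
        ]
        self.dec_layers = [
            nn.Upsample1d(size=21), nn.ConvTranspose1d(256, 128, 3, rng=rng),
            nn.Upsample1d(size=47), nn.ConvTranspose1d(128, 64, 3, rng=rng),
            nn.Upsample1d(size=98), nn.ConvTranspose1d(64, 6, 3, rng=rng),
        ]
        self.act_enc = [nn.GELU() for _ in range(3)]
        self.act_dec = [nn.GELU() for _ in range(2)]  # last layer is linear

    def _run(self, layers, acts, x, record=None):
        conv_i = 0
        for layer in layers:
            x = layer.forward(x)
            if isinstance(layer, (nn.Conv1d, nn.ConvTranspose1d)) and conv_i < len(acts):
                x = acts[conv_i].forward(x)
                conv_i += 1
            if record is not None:
                record.append(x.shape[1:])
        return x

    def encode(self, x, record=None):
        return self._run(self.enc_layers, self.act_enc, x, record)

    def decode(self, z, record=None):
        return self._run(self.dec_layers, self.act_dec, z, record)

    def forward(self, x, train=True):
        return self.decode(self.encode(x))

    def backward(self, grad):
        stack = []
        conv_i = 0
        for layer in self.dec_layers:
            stack.append(layer)
            if isinstance(layer, nn.ConvTranspose1d) and conv_i < len(self.act_dec):
                stack.append(self.act_dec[conv_i])
                conv_i += 1
        conv_i = 0
        enc_stack = []
        for layer in self.enc_layers:
            enc_stack.append(layer)
            if isinstance(layer, nn.Conv1d) and conv_i < len(self.act_enc):
                enc_stack.append(self.act_enc[conv_i])
                conv_i += 1
        for layer in reversed(enc_stack + stack):
            grad = layer.backward(grad)
        return grad


def _iterate_minibatches(n, batch_size, rng):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def train_ae(values: np.ndarray, hyper: TrainHyper, seed: int = 0):
    """Train an autoencoder on one class's windows; returns (model, history)."""
    if len(values) == 0:
        raise ValueError("cannot train on an empty class")
    values = np.asarray(values, dtype=nn.layers.DTYPE)
    rng = np.random.default_rng(seed)
    model = Autoencoder(rng)
    opt = nn.Adam(model.params(), lr=hyper.lr)
    history = []
    for _ in range(hyper.epochs):
        losses = []
        for batch in _iterate_minibatches(len(values), hyper.batch_size, rng):
            x = values[batch]
            model.zero_grad()
            out = model.forward(x)
            loss, grad = nn.mse(out, x)
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def ae_generate(model: Autoencoder, source_values: np.ndarray, n_new: int,
                jitter_sd: float = 0.1, seed: int = 0) -> np.ndarray:
    """Decode jittered latent codes of randomly chosen real windows."""
    if n_new == 0:
        return np.zeros((0, 6, 100))
    rng = np.random.default_rng(seed)
    latents = model.encode(np.asarray(source_values, dtype=nn.layers.DTYPE))
    latent_sd = latents.std(axis=0, keepdims=True)
    idx = rng.integers(0, len(source_values), size=n_new)
    z = latents[idx]
    if jitter_sd > 0:
        z = z + rng.normal(0, 1, size=z.shape) * (jitter_sd * latent_sd)
    return np.clip(model.decode(z), -1.0, 1.0)


class VAE(nn.Module):
    """Length-preserving convolutional VAE with a (64, 128) Gaussian latent."""

    def __init__(self, rng: np.random.Generator):
        self.enc = [
            nn.Conv1d(6, 64, 5, padding=2, rng=rng), nn.GELU(),
            nn.Conv1d(64, 64, 5, padding=2, rng=rng), nn.GELU(),
            nn.Conv1d(64, 64, 3, padding=1, rng=rng), nn.GELU(),
            nn.Conv1d(64, 64, 3, padding=1, rng=rng), nn.GELU(),
            nn.MaxPool1d(2),
        ]
        self.fc_mu = nn.Linear(50, 128, rng=rng)
        self.fc_logvar = nn.Linear(50, 128, rng=rng, zero_init=True)
        self.fc_dec = nn.Linear(128, 50, rng=rng)
        self.dec = [
            nn.Upsample1d(size=100),
            nn.Conv1d(64, 64, 3, padding=1, rng=rng), nn.GELU(),
            nn.Conv1d(64, 64, 3, padding=1, rng=rng), nn.GELU(),
            nn.Conv1d(64, 64, 5, padding=2, rng=rng), nn.GELU(),
            nn.Conv1d(64, 6, 5, padding=2, rng=rng),
        ]

    def encode(self, x, record=None):
        for layer in self.enc:
            x = layer.forward(x)
            if record is not None and not isinstance(layer, nn.GELU):
                record.append(x.shape[1:])
        mu = self.fc_mu.forward(x)
        logvar = self.fc_logvar.forward(x)
        return mu, logvar

    def decode(self, z, record=None):
        h = self.fc_dec.forward(z)
        if record is not None:
            record.append(h.shape[1:])
        for layer in self.dec:
            h = layer.forward(h)
            if record is not None and not isinstance(layer, nn.GELU):
                record.append(h.shape[1:])
        return h

    def backward_decode(self, grad):
        for layer in reversed(self.dec):
            grad = layer.backward(grad)
        return self.fc_dec.backward(grad)

    def backward_encode(self, g_mu, g_logvar):
        grad = self.fc_mu.backward(g_mu) + self.fc_logvar.backward(g_logvar)
        for layer in reversed(self.enc):
            grad = layer.backward(grad)
        return grad


def kl_standard_normal(mu: np.ndarray, logvar: np.ndarray):
    """KL(N(mu, sigma^2) || N(0, 1)) summed over latent dims, mean over batch.

    Returns (value, d/dmu, d/dlogvar).
    """
    n = mu.shape[0]
    kl = -0.5 * (1.0 + logvar - mu**2 - np.exp(logvar))
    return float(kl.sum() / n), mu / n, -0.5 * (1.0 - np.exp(logvar)) / n


def train_vae(values: np.ndarray, hyper: TrainHyper, beta: float = 1.0,
              seed: int = 0):
    """Train a VAE on one class's windows; returns (model, history).

    History entries are (total, reconstruction MSE, KL) per epoch.  The
    reconstruction term is the per-element MSE scaled by the element
    count so it is commensurate with the summed KL.
    """
    if len(values) == 0:
        raise ValueError("cannot train on an empty class")
    values = np.asarray(values, dtype=nn.layers.DTYPE)
    rng = np.random.default_rng(seed)
    model = VAE(rng)
    opt = nn.Adam(model.params(), lr=hyper.lr)
    d = values.shape[1] * values.shape[2]
    history = []
    for _ in range(hyper.epochs):
        ep = np.zeros(3)
        nb = 0
        for batch in _iterate_minibatches(len(values), hyper.batch_size, rng):
            x = values[batch]
            model.zero_grad()
            mu, logvar = model.encode(x)
            eps = rng.normal(size=mu.shape).astype(nn.layers.DTYPE)
            z = mu + np.exp(0.5 * logvar) * eps
            out = model.decode(z)
            mse_val, g_out = nn.mse(out, x)
            recon = mse_val * d  # per-sample summed squared error (batch mean)
            g_out = g_out * d
            kl, g_mu_kl, g_logvar_kl = kl_standard_normal(mu, logvar)
            g_z = model.backward_decode(g_out)
            g_mu = g_z + beta * g_mu_kl
            g_logvar = g_z * eps * 0.5 * np.exp(0.5 * logvar) + beta * g_logvar_kl
            model.backward_encode(g_mu, g_logvar)
            opt.step()
            ep += (recon + beta * kl, recon, kl)
            nb += 1
        history.append(tuple(ep / nb))
    return model, history


def vae_generate(model: VAE, n_new: int, seed: int = 0,
                 z: np.ndarray | None = None) -> np.ndarray:
    """Decode prior draws z ~ N(0, I); ``z`` is a test hook."""
    if n_new == 0:
        return np.zeros((0, 6, 100))
    if z is None:
        z = np.random.default_rng(seed).normal(size=(n_new, *VAE_BOTTLENECK_SHAPE))
    return np.clip(model.decode(np.asarray(z, dtype=nn.layers.DTYPE)), -1.0, 1.0)


class _PerClassDeepAugmenter(BaseAugmenter):
    """Shared fit/sample logic for the per-class AE and VAE augmenters."""

    def fit(self, dataset: WindowDataset, y=None):
        self.models_ = {}
        self.history_ = {}
        self.train_values_ = {}
        for label in (LABEL_ADL, LABEL_FALL):
            vals = dataset.values[dataset.labels == label]
            if len(vals) == 0:
                raise ValueError(f"class {label} has no training windows")
            self.train_values_[label] = vals
            model, hist = self._train(vals, label)
            self.models_[label] = model
            self.history_[label] = hist
        return self

    def sample(self, n_fall: int, n_adl: int, seed: int = 0) -> WindowDataset:
        parts = []
        for label, count in ((LABEL_FALL, n_fall), (LABEL_ADL, n_adl)):
            vals = self._generate(label, count, seed + label)
            parts.append(self._package(vals, label))
        return WindowDataset.concat(parts)


class AutoencoderAugmenter(_PerClassDeepAugmenter):
    name = "AE"
    clip_output = False  # ae_generate already clips

    def __init__(self, hyper: TrainHyper | None = None, jitter_sd: float = 0.1,
                 seed: int = 0):
        self.hyper = hyper or TrainHyper(lr=3e-4, epochs=100)
        self.jitter_sd = jitter_sd
        self.seed = seed

    def _train(self, vals, label):
        return train_ae(vals, self.hyper, seed=self.seed + label)

    def _generate(self, label, count, seed):
        return ae_generate(self.models_[label], self.train_values_[label], count,
                           jitter_sd=self.jitter_sd, seed=seed)


class VAEAugmenter(_PerClassDeepAugmenter):
    name = "VAE"
    clip_output = False  # vae_generate already clips

    def __init__(self, hyper: TrainHyper | None = None, beta: float = 1.0,
                 seed: int = 0):
        self.hyper = hyper or TrainHyper(lr=5e-4, epochs=100)
        self.beta = beta
        self.seed = seed

    def _train(self, vals, label):
        return train_vae(vals, self.hyper, beta=self.beta, seed=self.seed + label)

    def _generate(self, label, count, seed):
        return vae_generate(self.models_[label], count, seed=seed)
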