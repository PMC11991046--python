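"""Conditional denoising diffusion model with a 1-D U-Net noise predictor.

Forward process: a Markov chain that corrupts a window x0 with Gaussian
noise over T steps with per-step variances beta_t (linear schedule); the
closed-form jump to step t is

    x_t = sqrt(alpha_bar_t) x0 + sqrt(1 - alpha_bar_t) eps,

with alpha_t = 1 - beta_t and alpha_bar_t their cumulative product.  The
U-Net is trained to predict eps from (x_t, t, class); sampling runs the
ancestral reverse chain from pure noise with sigma_t = sqrt(beta_t).

The U-Net has two resolution levels (100 -> 50 -> 25 and back), each a
length-preserving convolution (kernel 3) + group normalization + GELU +
single-head temporal self-attention; skip connections concatenate encoder
features into the decoder.  Timestep information enters through a
sinusoidal embedding, summed with a learned 2-entry class embedding and
injected additively per level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .. import nn
from ..config import TrainHyper
from ..data import LABEL_ADL, LABEL_FALL, WindowDataset
from . import BaseAugmenter


@dataclass
class DiffusionSchedule:
    beta: np.ndarray        # (T,)
    alpha: np.ndarray       # 1 - beta
    alpha_bar: np.ndarray   # cumulative product of alpha

    @property
    def T(self) -> int:
        return len(self.beta)


def make_schedule(T: int = 1000, beta_start: float = 1e-4,
                  beta_end: float = 0.02) -> DiffusionSchedule:
    """Linear beta schedule with a numerically stable cumulative product."""
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    alpha_bar = np.exp(np.cumsum(np.log(alpha)))
    return DiffusionSchedule(beta=beta, alpha=alpha, alpha_bar=alpha_bar)


def forward_noise(x0: np.ndarray, t: int, schedule: DiffusionSchedule,
                  noise: np.ndarray) -> np.ndarray:
    """Closed-form jump to timestep t (1-based), equal to t iterated steps."""
    if not (1 <= t <= schedule.T):
        raise ValueError(f"t must be in [1, {schedule.T}], got {t}")
    if noise.shape != x0.shape:
        raise ValueError("noise must match x0's shape")
    ab = schedule.alpha_bar[t - 1]
    return math.sqrt(ab) * x0 + math.sqrt(1.0 - ab) * noise


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Standard sinusoidal timestep embedding, shape (len(t), dim)."""
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / half)
    ang = np.asarray(t, dtype=float)[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(nn.layers.DTYPE)


class _CondBlock(nn.Module):
    """Conv(k3, same) + GroupNorm + GELU + embedding injection + attention."""

    def __init__(self, in_ch, out_ch, emb_dim, rng, groups=8):
        self.conv = nn.Conv1d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.norm = nn.GroupNorm(groups, out_ch)
        self.act = nn.GELU()
        self.emb_proj = nn.Linear(emb_dim, out_ch, rng=rng)
        self.attn = nn.SelfAttention1d(out_ch, rng=rng)

    def forward(self, x, emb, train=True):
        h = self.act.forward(self.norm.forward(self.conv.forward(x)))
        h = h + self.emb_proj.forward(emb)[:, :, None]
        return self.attn.forward(h)

    def backward(self, grad):
        g = self.attn.backward(grad)
        self._last_emb_grad = self.emb_proj.backward(g.sum(axis=2))
        g = self.conv.backward(self.norm.backward(self.act.backward(g)))
        return g


class UNet1d(nn.Module):
    """Two-level conditional U-Net mapping (x_t, t, class) -> predicted noise."""

    def __init__(self, width: int = 64, emb_dim: int = 64,
                 rng: np.random.Generator | None = None, n_classes: int = 2):
        rng = rng if rng is not None else np.random.default_rng(0)
        w = width
        self.emb_dim = emb_dim
        self.class_table = nn.Param(rng.normal(0, 0.02, size=(n_classes, emb_dim)))
        self.down0 = _CondBlock(6, w, emb_dim, rng)
        self.pool0 = nn.MaxPool1d(2)
        self.down1 = _CondBlock(w, 2 * w, emb_dim, rng)
        self.pool1 = nn.MaxPool1d(2)
        self.mid = _CondBlock(2 * w, 2 * w, emb_dim, rng)
        self.up_interp1 = nn.Upsample1d(scale=2)
        self.up1 = _CondBlock(4 * w, 2 * w, emb_dim, rng)
        self.up_interp0 = nn.Upsample1d(scale=2)
        self.up0 = _CondBlock(3 * w, w, emb_dim, rng)
        self.out_conv = nn.Conv1d(w, 6, 3, padding=1, rng=rng, zero_init=True)
        self.width = w

    def forward(self, x, t, labels, train=True):
        emb = sinusoidal_embedding(np.atleast_1d(t), self.emb_dim)
        if emb.shape[0] == 1 and x.shape[0] > 1:
            emb = np.repeat(emb, x.shape[0], axis=0)
        emb = emb + self.class_table.value[np.asarray(labels, dtype=int)]
        self._labels = np.asarray(labels, dtype=int)
        h0 = self.down0.forward(x, emb)                    # (n, w, 100)
        h1 = self.down1.forward(self.pool0.forward(h0), emb)   # (n, 2w, 50)
        hm = self.mid.forward(self.pool1.forward(h1), emb)     # (n, 2w, 25)
        u1 = np.concatenate([self.up_interp1.forward(hm), h1], axis=1)
        h2 = self.up1.forward(u1, emb)                     # (n, 2w, 50)
        u0 = np.concatenate([self.up_interp0.forward(h2), h0], axis=1)
        h3 = self.up0.forward(u0, emb)                     # (n, w, 100)
        return self.out_conv.forward(h3)

    def backward(self, grad):
        w = self.width
        g3 = self.out_conv.backward(grad)
        gu0 = self.up0.backward(g3)
        g2 = self.up_interp0.backward(gu0[:, :2 * w])
        g_h0_skip = gu0[:, 2 * w:]
        gu1 = self.up1.backward(g2)
        gm = self.up_interp1.backward(gu1[:, :2 * w])
        g_h1_skip = gu1[:, 2 * w:]
        g_h1 = self.pool1.backward(self.mid.backward(gm)) + g_h1_skip
        g_h0 = self.pool0.backward(self.down1.backward(g_h1)) + g_h0_skip
        gx = self.down0.backward(g_h0)
        # class-table gradient: the embedding feeds every block additively,
        # so its gradient is the sum of the blocks' embedding-path gradients
        # (the sinusoidal time features carry no parameters)
        g_emb = sum(blk._last_emb_grad
                    for blk in (self.down0, self.down1, self.mid, self.up1, self.up0))
        np.add.at(self.class_table.grad, self._labels, g_emb)
        return gx


class DDPM:
    """Trainable conditional DDPM bundling the U-Net and its schedule."""

    def __init__(self, schedule: DiffusionSchedule, width: int = 64,
                 seed: int = 0):
        self.schedule = schedule
        self.rng = np.random.default_rng(seed)
        self.net = UNet1d(width=width, rng=self.rng)

    def predict_noise(self, x_t, t, labels, train=True):
        return self.net.forward(x_t, t, labels, train=train)

    def train_epochs(self, values: np.ndarray, labels: np.ndarray,
                     hyper: TrainHyper) -> list[float]:
        if len(values) == 0:
            raise ValueError("cannot train a diffusion model on an empty dataset")
        values = np.asarray(values, dtype=nn.layers.DTYPE)
        opt = nn.Adam(self.net.params(), lr=hyper.lr)
        T = self.schedule.T
        history = []
        for _ in range(hyper.epochs):
            idx = self.rng.permutation(len(values))
            losses = []
            for i in range(0, len(values), hyper.batch_size):
                b = idx[i:i + hyper.batch_size]
                x0 = values[b]
                y = labels[b]
                t = self.rng.integers(1, T + 1, size=len(b))
                eps = self.rng.normal(size=x0.shape).astype(nn.layers.DTYPE)
                ab = self.schedule.alpha_bar[t - 1][:, None, None].astype(nn.layers.DTYPE)
                x_t = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps
                self.net.zero_grad()
                pred = self.net.forward(x_t, t, y)
                loss, grad = nn.mse(pred, eps)
                self.net.backward(grad)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.history_ = getattr(self, "history_", []) + history
        return history

    def sample(self, n: int, label: int, seed: int = 0,
               clip_denoised: bool = True) -> np.ndarray:
        """Ancestral reverse-chain sampling, clipped to [-1, 1].

        Each step removes the predicted noise and adds sigma_t = sqrt(beta_t)
        fresh noise.  With ``clip_denoised`` (standard practice in
        diffusion samplers) the implied clean signal is clipped to
        the data range [-1, 1] before the posterior mean is formed, which
        keeps the chain stable for lightly trained models.
        """
        if n == 0:
            return np.zeros((0, 6, 100))
        rng = np.random.default_rng(seed)
        sch = self.schedule
        x = rng.normal(size=(n, 6, 100)).astype(nn.layers.DTYPE)
        labels = np.full(n, label, dtype=int)
        for t in range(sch.T, 0, -1):
            eps_hat = self.net.forward(x, t, labels, train=False)
            a = sch.alpha[t - 1]
            ab = sch.alpha_bar[t - 1]
            if clip_denoised:
                x0_hat = np.clip((x - math.sqrt(1.0 - ab) * eps_hat)
                                 / math.sqrt(ab), -1.0, 1.0)
                eps_hat = (x - math.sqrt(ab) * x0_hat) / math.sqrt(1.0 - ab)
            x = (x - (1.0 - a) / math.sqrt(1.0 - ab) * eps_hat) / math.sqrt(a)
            if t > 1:
                x = (x + math.sqrt(sch.beta[t - 1])
                     * rng.normal(size=x.shape)).astype(nn.layers.DTYPE)
        return np.clip(x, -1.0, 1.0)


class DiffusionAugmenter(BaseAugmenter):
    name = "DM"
    clip_output = False  # DDPM.sample already clips

    def __init__(self, hyper: TrainHyper | None = None, timesteps: int = 1000,
                 beta_start: float = 1e-4, beta_end: float = 0.02,
                 width: int = 64, seed: int = 0):
        self.hyper = hyper or TrainHyper(lr=3e-4, epochs=300)
        self.timesteps = timesteps
        self.beta_start = beta_start
        self.beta_end = beta_end
        self.width = width
        self.seed = seed

    def fit(self, dataset: WindowDataset, y=None):
        schedule = make_schedule(self.timesteps, self.beta_start, self.beta_end)
        self.model_ = DDPM(schedule, width=self.width, seed=self.seed)
        self.history_ = self.model_.train_epochs(dataset.values, dataset.labels,
                                                 self.hyper)
        return self

    def sample(self, n_fall: int, n_adl: int, seed: int = 0) -> WindowDataset:
        fall = self.model_.sample(n_fall, LABEL_FALL, seed=seed)
        adl = self.model_.sample(n_adl, LABEL_ADL, seed=seed + 1)
        return WindowDataset.concat([
            self._package(fall, LABEL_FALL),
            self._package(adl, LABEL_ADL),
        ])
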