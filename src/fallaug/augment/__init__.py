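"""Augmenter interface shared by all generators.

Every augmenter is a scikit-learn-style estimator: ``fit(dataset)`` learns
from (normalized) real training windows, ``sample(n_fall, n_adl, seed)``
returns a synthetic :class:`~fallaug.data.WindowDataset` with the
requested per-class counts and provenance ``synthetic/<name>``.

The per-class counts come from :func:`compute_plan`: with falls the
minority class, generating ``n_real_adl`` synthetic falls and
``n_real_fall`` synthetic ADL windows is the unique solution that (a)
balances the combined real+synthetic training set and (b) makes the total
synthetic count equal the real training size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ..data import WindowDataset


@dataclass(frozen=True)
class AugmentationPlan:
    n_synth_fall: int
    n_synth_adl: int

    @property
    def total(self) -> int:
        return self.n_synth_fall + self.n_synth_adl


def compute_plan(n_real_adl: int, n_real_fall: int) -> AugmentationPlan:
    """Per-class synthetic counts balancing the combined training set.

    Solves n_fall + s_f = n_adl + s_a and s_f + s_a = n_adl + n_fall,
    giving s_f = n_real_adl and s_a = n_real_fall.
    """
    if n_real_fall > n_real_adl:
        raise ValueError("falls are assumed to be the minority class "
                         f"({n_real_fall} > {n_real_adl})")
    if n_real_adl < 0 or n_real_fall < 0:
        raise ValueError("counts must be nonnegative")
    return AugmentationPlan(n_synth_fall=n_real_adl, n_synth_adl=n_real_fall)


class BaseAugmenter(BaseEstimator):
    """Common fit/sample surface. Subclasses set ``name``."""

    name: str = "base"

    def fit(self, dataset: WindowDataset, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def sample(self, n_fall: int, n_adl: int, seed: int = 0) -> WindowDataset:  # pragma: no cover
        raise NotImplementedError

    def sample_plan(self, plan: AugmentationPlan, seed: int = 0) -> WindowDataset:
        return self.sample(plan.n_synth_fall, plan.n_synth_adl, seed=seed)

    def _package(self, values: np.ndarray, label: int,
                 subject_ids=None) -> WindowDataset:
        n = len(values)
        if subject_ids is None:
            subject_ids = np.full(n, -1, dtype=int)
        return WindowDataset(
            values=np.clip(values, -1.0, 1.0) if self.clip_output else values,
            labels=np.full(n, label, dtype=int),
            subject_ids=np.asarray(subject_ids, dtype=int),
            provenance=np.array([f"synthetic/{self.name}"] * n, dtype=object),
        )

    clip_output: bool = True


def get_augmenter(name: str, cfg=None, rng_seed: int = 0) -> "BaseAugmenter | None":
    """Instantiate an augmenter by its configuration name.

    ``BL`` returns None (no augmentation); ``DTF`` is handled at the
    evaluation layer as the average over the three transform augmenters.
    """
    from .classic import (PermutationAugmenter, RotationAugmenter,
                          ScalingAugmenter, SmoteAugmenter)
    from .autoencoder import AutoencoderAugmenter, VAEAugmenter
    from .diffusion import DiffusionAugmenter

    if cfg is None:
        from ..config import RunConfig
        cfg = RunConfig()
    if name == "BL":
        return None
    if name == "rotation":
        return RotationAugmenter()
    if name == "scaling":
        return ScalingAugmenter()
    if name == "permutation":
        return PermutationAugmenter()
    if name == "SMOTE":
        return SmoteAugmenter(k=cfg.smote_k, seed=cfg.smote_seed)
    if name == "AE":
        return AutoencoderAugmenter(hyper=cfg.ae, jitter_sd=cfg.latent_jitter_sd,
                                    seed=rng_seed)
    if name == "VAE":
        return VAEAugmenter(hyper=cfg.vae, seed=rng_seed)
    if name == "DM":
        return DiffusionAugmenter(hyper=cfg.ddpm, timesteps=cfg.timesteps,
                                  beta_start=cfg.beta_start, beta_end=cfg.beta_end,
                                  width=cfg.unet_width, seed=rng_seed)
    raise ValueError(f"unknown augmenter {name!r}; valid: BL, DTF, SMOTE, AE, VAE, DM "
                     "(or rotation/scaling/permutation)")


DTF_MEMBERS = ("rotation", "scaling", "permutation")
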