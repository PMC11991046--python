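"""Transformation-based augmenters and SMOTE.

The three signal transforms act on one window at a time:

* rotation — the accelerometer triplet and the gyroscope triplet are each
  premultiplied by an independent uniformly random 3-D rotation (drawn
  with the correct invariant measure), preserving per-sample norms;
* scaling — one factor ~ Uniform(0, 2) per window multiplies all six
  channels;
* permutation — the window is cut into four equal blocks which are
  reordered by a random permutation shared across channels.

SMOTE interpolates flattened 600-dimensional windows between a base
sample and one of its k Euclidean nearest neighbours within the class:
x_new = x_chosen + (x_nearest - x_chosen) * delta, delta ~ Uniform(0, 1),
cycling the base through every class member.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.neighbors import NearestNeighbors

from ..data import LABEL_ADL, LABEL_FALL, WindowDataset
from . import BaseAugmenter


def rotate_window(values: np.ndarray, seed: int = 0,
                  rotations: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Rotate accel and gyro triplets independently.

    ``rotations`` is a test hook: a pair of 3x3 matrices (accel, gyro)
    overriding the random draw.
    """
    if rotations is None:
        rng = np.random.default_rng(seed)
        r_acc = Rotation.random(rng=rng).as_matrix()
        r_gyr = Rotation.random(rng=rng).as_matrix()
    else:
        r_acc, r_gyr = rotations
    out = np.empty_like(values)
    out[:3] = r_acc @ values[:3]
    out[3:] = r_gyr @ values[3:]
    return out


def scale_window(values: np.ndarray, seed: int = 0,
                 factor: float | None = None) -> np.ndarray:
    """Multiply all channels by one factor ~ Uniform(0, 2) (hook: ``factor``)."""
    if factor is None:
        factor = np.random.default_rng(seed).uniform(0.0, 2.0)
    return values * factor


def permute_window(values: np.ndarray, n_parts: int = 4, seed: int = 0,
                   order: np.ndarray | None = None) -> np.ndarray:
    """Reorder equal-length blocks by a random permutation (hook: ``order``)."""
    length = values.shape[1]
    if length % n_parts:
        raise ValueError(f"window length {length} not divisible by {n_parts} parts")
    if order is None:
        order = np.random.default_rng(seed).permutation(n_parts)
    blocks = np.split(values, n_parts, axis=1)
    return np.concatenate([blocks[i] for i in order], axis=1)


class _TransformAugmenter(BaseAugmenter):
    """Applies one transform to real windows resampled with replacement."""

    clip_output = False  # transforms operate on whatever scale they are given

    def fit(self, dataset: WindowDataset, y=None):
        self.fall_ = dataset.values[dataset.labels == LABEL_FALL]
        self.adl_ = dataset.values[dataset.labels == LABEL_ADL]
        return self

    def _apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def sample(self, n_fall: int, n_adl: int, seed: int = 0) -> WindowDataset:
        rng = np.random.default_rng(seed)
        parts = []
        for pool, label, count in ((self.fall_, LABEL_FALL, n_fall),
                                   (self.adl_, LABEL_ADL, n_adl)):
            if count and not len(pool):
                raise ValueError("cannot augment an empty class")
            idx = rng.integers(0, len(pool), size=count) if count else []
            vals = np.stack([self._apply(pool[i], rng) for i in idx]) if count \
                else np.zeros((0, 6, 100))
            parts.append(self._package(vals, label))
        return WindowDataset.concat(parts)


class RotationAugmenter(_TransformAugmenter):
    name = "rotation"

    def _apply(self, values, rng):
        r_acc = Rotation.random(rng=rng).as_matrix()
        r_gyr = Rotation.random(rng=rng).as_matrix()
        return rotate_window(values, rotations=(r_acc, r_gyr))


class ScalingAugmenter(_TransformAugmenter):
    name = "scaling"

    def _apply(self, values, rng):
        return scale_window(values, factor=rng.uniform(0.0, 2.0))


class PermutationAugmenter(_TransformAugmenter):
    name = "permutation"

    def __init__(self, n_parts: int = 4):
        self.n_parts = n_parts

    def _apply(self, values, rng):
        return permute_window(values, n_parts=self.n_parts,
                              order=rng.permutation(self.n_parts))


def smote_generate(class_values: np.ndarray, n_new: int, k: int = 5,
                   seed: int = 42, delta: float | None = None) -> np.ndarray:
    """Interpolated samples within one class.

    ``class_values`` is (n, 6, 100); distances are Euclidean on flattened
    channel-major 600-vectors.  Base samples are cycled so every class
    member is used; the neighbour is drawn uniformly from the k nearest.
    ``delta`` is a test hook fixing the interpolation coefficient.
    """
    n = len(class_values)
    if n <= k:
        raise ValueError(f"need more than k={k} samples per class, got {n}")
    rng = np.random.default_rng(seed)
    flat = class_values.reshape(n, -1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(flat)
    neigh = nn.kneighbors(flat, return_distance=False)[:, 1:]  # drop self
    out = np.empty((n_new, flat.shape[1]))
    for j in range(n_new):
        base = j % n
        near = neigh[base, rng.integers(0, k)]
        d = rng.uniform(0.0, 1.0) if delta is None else delta
        out[j] = flat[base] + (flat[near] - flat[base]) * d
    return out.reshape(n_new, *class_values.shape[1:])


class SmoteAugmenter(BaseAugmenter):
    name = "SMOTE"
    clip_output = False  # interpolation cannot leave the data range

    def __init__(self, k: int = 5, seed: int = 42):
        self.k = k
        self.seed = seed

    def fit(self, dataset: WindowDataset, y=None):
        self.fall_ = dataset.values[dataset.labels == LABEL_FALL]
        self.adl_ = dataset.values[dataset.labels == LABEL_ADL]
        return self

    def sample(self, n_fall: int, n_adl: int, seed: int | None = None) -> WindowDataset:
        seed = self.seed if seed is None else seed
        parts = []
        for pool, label, count in ((self.fall_, LABEL_FALL, n_fall),
                                   (self.adl_, LABEL_ADL, n_adl)):
            vals = smote_generate(pool, count, k=self.k, seed=seed + label) if count \
                else np.zeros((0, 6, 100))
            parts.append(self._package(vals, label))
        return WindowDataset.concat(parts)
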