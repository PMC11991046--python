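"""Windowing and min-max normalization of IMU recordings.

Fall recordings are cut into 100-sample windows with 50 % overlap
(stride 50).  ADL recordings shorter than 1000 samples use the same
sliding window; longer ones are split into ten equal segments with one
randomly placed 100-sample window per segment, which caps the
contribution of very long recordings.  Normalization is per-channel
min-max to [-1, 1], fitted on a training split only and applied with
clipping to train, test and synthetic data alike.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import child_seed
from .data import (LABEL_ADL, LABEL_FALL, N_CHANNELS, RawRecording,
                   WINDOW_LEN, WindowDataset)

STRIDE = WINDOW_LEN // 2           # 50 % overlap
LONG_ADL_THRESHOLD = 1000          # samples; ~54.35 s at 18.4 Hz
N_LONG_SEGMENTS = 10


def n_sliding_windows(n_samples: int, window: int = WINDOW_LEN,
                      stride: int = STRIDE) -> int:
    """Closed-form window count of the sliding rule: floor((n-w)/s) + 1."""
    if n_samples < window:
        return 0
    return (n_samples - window) // stride + 1


def _starts_sliding(n: int, window: int, stride: int) -> list[int]:
    return [s for s in range(0, n - window + 1, stride)]


def _windows_from_starts(rec: RawRecording, starts, label: int,
                         window: int) -> WindowDataset:
    vals = np.stack([rec.samples[s:s + window].T for s in starts]) if starts \
        else np.zeros((0, N_CHANNELS, window))
    n = len(starts)
    return WindowDataset(
        values=vals,
        labels=np.full(n, label, dtype=int),
        subject_ids=np.full(n, rec.subject_id, dtype=int),
        provenance=np.array(["real"] * n, dtype=object),
        source_keys=np.array([(rec.activity_id, rec.trial_id, s) for s in starts],
                             dtype=int).reshape(n, 3),
    )


def segment_fall(rec: RawRecording, window: int = WINDOW_LEN,
                 overlap: float = 0.5) -> WindowDataset:
    """Sliding-window segmentation of a fall recording (50 % overlap)."""
    stride = int(round(window * (1.0 - overlap)))
    if rec.n_samples < window:
        warnings.warn(f"recording shorter than window ({rec.n_samples} < {window}); "
                      "no windows produced")
        return WindowDataset.empty()
    starts = _starts_sliding(rec.n_samples, window, stride)
    return _windows_from_starts(rec, starts, LABEL_FALL, window)


def segment_adl(rec: RawRecording, window: int = WINDOW_LEN, overlap: float = 0.5,
                long_threshold: int = LONG_ADL_THRESHOLD,
                n_segments: int = N_LONG_SEGMENTS, seed: int = 0) -> WindowDataset:
    """Segment an ADL recording.

    Short recordings (< ``long_threshold`` samples) use the sliding rule;
    long ones are divided into ``n_segments`` equal parts with one window
    drawn uniformly inside each part.
    """
    n = rec.n_samples
    stride = int(round(window * (1.0 - overlap)))
    if n < window:
        warnings.warn(f"recording shorter than window ({n} < {window}); "
                      "no windows produced")
        return WindowDataset.empty()
    if n < long_threshold:
        starts = _starts_sliding(n, window, stride)
    else:
        bounds = [n * i // n_segments for i in range(n_segments + 1)]
        if min(b2 - b1 for b1, b2 in zip(bounds, bounds[1:])) < window:
            warnings.warn("segments shorter than the window; falling back to "
                          "sliding windows")
            starts = _starts_sliding(n, window, stride)
        else:
            rng = np.random.default_rng(seed)
            starts = [int(rng.integers(b1, b2 - window + 1))
                      for b1, b2 in zip(bounds, bounds[1:])]
    return _windows_from_starts(rec, starts, LABEL_ADL, window)


def windows_from_recordings(recordings: list[RawRecording],
                            seed: int = 0) -> WindowDataset:
    """Segment a whole cohort, labelling windows by their recording's class."""
    parts = []
    for i, rec in enumerate(recordings):
        if rec.is_fall:
            parts.append(segment_fall(rec))
        else:
            parts.append(segment_adl(
                rec, seed=child_seed(seed, f"segment-{rec.subject_id}-"
                                           f"{rec.activity_id}-{rec.trial_id}-{i}")))
    return WindowDataset.concat(parts)


class WindowNormalizer(BaseEstimator, TransformerMixin):
    """Per-channel min-max scaler to [-1, 1] with out-of-range clipping.

    Fitted attributes
    -----------------
    min_, max_ : (6,) per-channel extrema pooled over the fitted windows
    degenerate_ : (6,) bool mask of channels with max == min (mapped to 0)
    fit_scope : free-text tag recording which split produced the stats
    """

    def __init__(self, fit_scope: str = "unspecified"):
        self.fit_scope = fit_scope

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("fit requires a nonempty (n, channels, length) array")
        self.min_ = X.min(axis=(0, 2))
        self.max_ = X.max(axis=(0, 2))
        self.degenerate_ = self.max_ == self.min_
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        span = np.where(self.degenerate_, 1.0, self.max_ - self.min_)
        out = 2.0 * (X - self.min_[None, :, None]) / span[None, :, None] - 1.0
        out[:, self.degenerate_, :] = 0.0
        return np.clip(out, -1.0, 1.0)

    def transform_dataset(self, ds: WindowDataset) -> WindowDataset:
        return WindowDataset(self.transform(ds.values), ds.labels, ds.subject_ids,
                             ds.provenance, ds.source_keys)


def fit_normalization(train: WindowDataset | np.ndarray,
                      fit_scope: str = "train") -> WindowNormalizer:
    X = train.values if isinstance(train, WindowDataset) else train
    return WindowNormalizer(fit_scope=fit_scope).fit(X)


def apply_normalization(ds: WindowDataset, norm: WindowNormalizer) -> WindowDataset:
    return norm.transform_dataset(ds)
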