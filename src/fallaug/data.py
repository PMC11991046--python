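"""In-memory containers for recordings and windowed datasets.

A *recording* is one continuous 6-channel IMU stream (accelerometer x/y/z
then gyroscope x/y/z) for one (subject, activity, trial).  A *window* is a
fixed 6 x 100 slice of a recording, the unit of classification and
generation.  Windows are stored columnarly in :class:`WindowDataset` as a
stacked array plus aligned metadata vectors, which keeps slicing,
concatenation and persistence cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: number of IMU channels (ax, ay, az, gx, gy, gz)
N_CHANNELS = 6
#: samples per classification window
WINDOW_LEN = 100
#: wrist IMU sampling rate of the target dataset, Hz
SAMPLING_RATE_HZ = 18.4

LABEL_ADL = 0
LABEL_FALL = 1
LABEL_NAMES = {LABEL_ADL: "ADL", LABEL_FALL: "FALL"}


@dataclass
class RawRecording:
    """One continuous stream for a (subject, activity, trial) triple."""

    subject_id: int
    activity_id: int
    trial_id: int
    samples: np.ndarray  # (n_samples, 6)
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    is_fall: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(f"samples must be (n, {N_CHANNELS}), got {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class WindowDataset:
    """Stack of labelled windows with subject and provenance metadata.

    Attributes
    ----------
    values : (n, 6, 100) float array
    labels : (n,) int array, 0 = ADL, 1 = FALL
    subject_ids : (n,) int array
    provenance : (n,) str array, ``"real"`` or ``"synthetic/<generator>"``
    source_keys : (n, 3) int array of (activity_id, trial_id, start_index);
        -1 where not applicable (e.g. generated windows)
    """

    values: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    provenance: np.ndarray
    source_keys: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = len(self.values)
        if self.source_keys is None:
            self.source_keys = np.full((n, 3), -1, dtype=np.int64)
        self.source_keys = np.asarray(self.source_keys, dtype=np.int64)
        if self.values.ndim != 3 or self.values.shape[1:] != (N_CHANNELS, WINDOW_LEN):
            if n:  # allow (0, ...) placeholder shapes for empty datasets
                raise ValueError(f"values must be (n, {N_CHANNELS}, {WINDOW_LEN})")
            self.values = self.values.reshape(0, N_CHANNELS, WINDOW_LEN)
        for name, arr in (("labels", self.labels), ("subject_ids", self.subject_ids),
                          ("provenance", self.provenance)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n windows {n}")
        if n and not np.isin(self.labels, [LABEL_ADL, LABEL_FALL]).all():
            raise ValueError("labels must be 0 (ADL) or 1 (FALL)")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def empty(cls) -> "WindowDataset":
        return cls(np.zeros((0, N_CHANNELS, WINDOW_LEN)), np.zeros(0, dtype=int),
                   np.zeros(0, dtype=int), np.array([], dtype=object))

    def class_counts(self) -> dict[str, int]:
        return {"ADL": int((self.labels == LABEL_ADL).sum()),
                "FALL": int((self.labels == LABEL_FALL).sum())}

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def subset(self, mask_or_idx) -> "WindowDataset":
        idx = np.asarray(mask_or_idx)
        return WindowDataset(self.values[idx], self.labels[idx],
                             self.subject_ids[idx], self.provenance[idx],
                             self.source_keys[idx])

    @staticmethod
    def concat(parts: list["WindowDataset"]) -> "WindowDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            return WindowDataset.empty()
        return WindowDataset(
            np.concatenate([p.values for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.provenance for p in parts]),
            np.concatenate([p.source_keys for p in parts]),
        )

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write the dataset to a single ``.npz`` container (bit-exact)."""
        meta = json.dumps({"format": "fallaug-windows", "version": 1,
                           "n_windows": len(self)})
        with open(path, "wb") as fh:  # keep the exact path, no .npz appending
            np.savez(fh, values=self.values, labels=self.labels,
                     subject_ids=self.subject_ids,
                     provenance=self.provenance.astype(str),
                     source_keys=self.source_keys,
                     meta=np.array(meta))

    @classmethod
    def load(cls, path) -> "WindowDataset":
        try:
            with np.load(path, allow_pickle=False) as f:
                meta = json.loads(str(f["meta"]))
                if meta.get("format") != "fallaug-windows":
                    raise ValueError(f"{path}: not a fallaug window store")
                return cls(f["values"], f["labels"], f["subject_ids"],
                           f["provenance"].astype(object), f["source_keys"])
        except (KeyError, ValueError, OSError, json.JSONDecodeError) as exc:
            raise IOError(f"failed to load window dataset from {path}: {exc}") from exc
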