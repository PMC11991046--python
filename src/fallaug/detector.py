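"""1-D CNN fall detector and its evaluation metrics.

Architecture: three convolutional blocks — Conv1d(64 filters, kernel 3,
length-preserving) + batch normalization + ReLU + max-pool(2) + dropout —
followed by two fully connected layers (hidden width 128, output 2) with
a softmax head.  Trained with Adam and cross-entropy.  FALL is the
positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .config import TrainHyper
from .data import LABEL_ADL, LABEL_FALL, WindowDataset


@dataclass
class ConfusionMatrix:
    """Counts with FALL as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall and F1 from the confusion counts.

    Ratios with zero denominators are reported as 0.0 and flagged in the
    ``degenerate`` list.
    """
    degenerate = []
    total = cm.total
    accuracy = (cm.tp + cm.tn) / total if total else 0.0
    if cm.tp + cm.fp:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision = 0.0
        degenerate.append("precision")
    if cm.tp + cm.fn:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall = 0.0
        degenerate.append("recall")
    if precision + recall:
        f1 = 2.0 * recall * precision / (recall + precision)
    else:
        f1 = 0.0
        degenerate.append("f1")
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "degenerate": degenerate,
            "confusion": {"TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn}}


class _DetectorNet(nn.Module):
    def __init__(self, rng: np.random.Generator, dropout: float = 0.5,
                 fc_hidden: int = 128, filters: int = 64):
        f = filters
        self.blocks = []
        in_ch = 6
        for _ in range(3):
            self.blocks.append({
                "conv": nn.Conv1d(in_ch, f, 3, padding=1, rng=rng),
                "bn": nn.BatchNorm1d(f),
                "relu": nn.ReLU(),
                "pool": nn.MaxPool1d(2),
                "drop": nn.Dropout(dropout, rng),
            })
            in_ch = f
        self.flat = nn.Flatten()
        self.fc1 = nn.Linear(f * 12, fc_hidden, rng=rng)  # 100 -> 50 -> 25 -> 12
        self.relu_fc = nn.ReLU()
        self.fc2 = nn.Linear(fc_hidden, 2, rng=rng)

    def params(self):
        out = []
        for blk in self.blocks:
            out.extend(blk["conv"].params())
            out.extend(blk["bn"].params())
        out.extend(self.fc1.params())
        out.extend(self.fc2.params())
        return out

    def forward(self, x, train=True):
        for blk in self.blocks:
            x = blk["conv"].forward(x)
            x = blk["bn"].forward(x, train=train)
            x = blk["relu"].forward(x)
            x = blk["pool"].forward(x)
            x = blk["drop"].forward(x, train=train)
        x = self.flat.forward(x)
        x = self.relu_fc.forward(self.fc1.forward(x))
        return self.fc2.forward(x)

    def backward(self, grad):
        grad = self.fc2.backward(grad)
        grad = self.fc1.backward(self.relu_fc.backward(grad))
        grad = self.flat.backward(grad)
        for blk in reversed(self.blocks):
            grad = blk["drop"].backward(grad)
            grad = blk["pool"].backward(grad)
            grad = blk["relu"].backward(grad)
            grad = blk["bn"].backward(grad)
            grad = blk["conv"].backward(grad)
        return grad


class CNNFallDetector(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper around the convolutional detector.

    ``fit`` expects (n, 6, 100) windows already normalized to [-1, 1] and
    binary labels (1 = FALL); refuses single-class training sets because
    cross-entropy against one class learns nothing about the boundary.
    """

    def __init__(self, hyper: TrainHyper | None = None, dropout: float = 0.5,
                 fc_hidden: int = 128, seed: int = 0):
        self.hyper = hyper or TrainHyper(lr=3e-4, epochs=300)
        self.dropout = dropout
        self.fc_hidden = fc_hidden
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=nn.layers.DTYPE)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class; "
                             "cross-entropy training is degenerate")
        rng = np.random.default_rng(self.seed)
        self.net_ = _DetectorNet(rng, dropout=self.dropout, fc_hidden=self.fc_hidden)
        opt = nn.Adam(self.net_.params(), lr=self.hyper.lr)
        self.history_ = []
        for _ in range(self.hyper.epochs):
            idx = rng.permutation(len(X))
            losses = []
            for i in range(0, len(X), self.hyper.batch_size):
                b = idx[i:i + self.hyper.batch_size]
                if len(b) < 2:
                    continue  # BatchNorm needs at least two samples
                for p in self.net_.params():
                    p.grad[...] = 0.0
                logits = self.net_.forward(X[b], train=True)
                loss, grad = nn.cross_entropy(logits, y[b])
                self.net_.backward(grad)
                opt.step()
                losses.append(loss)
            self.history_.append(float(np.mean(losses)))
        self.classes_ = np.array([LABEL_ADL, LABEL_FALL])
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=nn.layers.DTYPE)
        out = []
        for i in range(0, len(X), 256):
            out.append(nn.softmax(self.net_.forward(X[i:i + 256], train=False)))
        return np.concatenate(out) if out else np.zeros((0, 2))

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


def train_detector(train: WindowDataset, hyper: TrainHyper | None = None,
                   seed: int = 0, dropout: float = 0.5,
                   fc_hidden: int = 128) -> CNNFallDetector:
    det = CNNFallDetector(hyper=hyper, dropout=dropout, fc_hidden=fc_hidden,
                          seed=seed)
    return det.fit(train.values, train.labels)


def evaluate_detector(model: CNNFallDetector, test: WindowDataset) -> dict:
    """Confusion matrix and the four headline metrics on a test set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test.values)
    y = test.labels
    cm = ConfusionMatrix(
        tp=int(((pred == LABEL_FALL) & (y == LABEL_FALL)).sum()),
        fp=int(((pred == LABEL_FALL) & (y == LABEL_ADL)).sum()),
        fn=int(((pred == LABEL_ADL) & (y == LABEL_FALL)).sum()),
        tn=int(((pred == LABEL_ADL) & (y == LABEL_ADL)).sum()),
    )
    return compute_metrics(cm)
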