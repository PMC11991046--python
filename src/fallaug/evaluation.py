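"""Evaluation protocols: LOGO-CV, TSTR, dispersion ratios, ratio sweeps.

Leave-one-group-out cross-validation partitions subjects into groups
(default 4; 17 subjects give sizes 4,4,4,5), holds each group out in
turn, and averages metrics over folds, so the detector is always tested
on subjects it never saw.  Within a fold the order of operations is:

1. subsample the real training windows to ``real_fraction`` (stratified
   by class, allocated across subjects by largest remainder, so the
   subject structure survives);
2. fit min-max normalization on that training subset only and apply it
   to train, test and synthetic data alike;
3. fit the augmenter on the normalized real training windows and draw
   the per-class synthetic counts of the balancing plan;
4. train the CNN detector on real+synthetic (or synthetic only for
   train-on-synthetic-test-on-real) and evaluate on the held-out real
   windows.

The dispersion statistics scalarize the within-class and between-class
scatter matrices by trace / dimension: with flattened 600-vectors X_k^i,
class means m_i, sizes N_i and priors P_i = N_i / N,

    S_W = sum_i P_i * (1/N_i) sum_k ||X_k^i - m_i||^2 / d
    S_B = 1/2 sum_i sum_j P_i P_j ||m_i - m_j||^2 / d
    ratio = S_B / S_W

A higher ratio over {synthetic fall, synthetic ADL} means better class
separation; a lower ratio over {real, synthetic} means higher realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .augment import DTF_MEMBERS, BaseAugmenter, compute_plan, get_augmenter
from .config import RunConfig, child_seed
from .data import LABEL_ADL, LABEL_FALL, WindowDataset
from .detector import CNNFallDetector, evaluate_detector
from .preprocessing import fit_normalization

METRIC_KEYS = ("accuracy", "precision", "recall", "f1")


# ---------------------------------------------------------------------------
# subject grouping
# ---------------------------------------------------------------------------

@dataclass
class CVSplit:
    """Subject -> group assignment for leave-one-group-out CV."""

    assignments: dict[int, int]
    n_groups: int

    def group_subjects(self, g: int) -> list[int]:
        return [s for s, gg in self.assignments.items() if gg == g]


def make_logo_splits(subject_ids, n_groups: int = 4, seed: int | None = None,
                     shuffle: bool = False) -> CVSplit:
    """Deal sorted subjects into groups of near-equal size (larger last).

    With ``shuffle`` the subject order is permuted with ``seed`` first;
    the default is the deterministic sorted assignment.
    """
    subjects = sorted(set(int(s) for s in subject_ids))
    if len(subjects) < n_groups:
        raise ValueError(f"{len(subjects)} subjects cannot fill {n_groups} groups")
    if shuffle:
        rng = np.random.default_rng(seed)
        subjects = [subjects[i] for i in rng.permutation(len(subjects))]
    n = len(subjects)
    base, extra = divmod(n, n_groups)
    sizes = [base] * (n_groups - extra) + [base + 1] * extra  # larger groups last
    assignments = {}
    pos = 0
    for g, size in enumerate(sizes):
        for s in subjects[pos:pos + size]:
            assignments[s] = g
        pos += size
    return CVSplit(assignments=assignments, n_groups=n_groups)


def subsample_stratified(ds: WindowDataset, fraction: float,
                         seed: int) -> WindowDataset:
    """Keep round(fraction * n) windows per class, spread across subjects.

    Within each class the per-subject keep counts follow the largest-
    remainder method on exact quotas, so every training subject stays
    represented and the per-class total is exact.
    """
    if fraction >= 1.0:
        return ds
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(ds), dtype=bool)
    for label in (LABEL_ADL, LABEL_FALL):
        cls_idx = np.flatnonzero(ds.labels == label)
        if not len(cls_idx):
            continue
        target = int(round(fraction * len(cls_idx)))
        target = max(target, 1)
        subj = ds.subject_ids[cls_idx]
        quotas = {}
        for s in np.unique(subj):
            quotas[s] = fraction * (subj == s).sum()
        floors = {s: int(np.floor(q)) for s, q in quotas.items()}
        remainder = target - sum(floors.values())
        by_frac = sorted(quotas, key=lambda s: quotas[s] - floors[s], reverse=True)
        counts = dict(floors)
        for s in by_frac[:max(remainder, 0)]:
            counts[s] += 1
        for s, c in counts.items():
            pool = cls_idx[subj == s]
            c = min(c, len(pool))
            keep[rng.choice(pool, size=c, replace=False)] = True
    return ds.subset(keep)


# ---------------------------------------------------------------------------
# fold pipeline
# ---------------------------------------------------------------------------

def _iter_folds(dataset: WindowDataset, split: CVSplit):
    for g in range(split.n_groups):
        test_subjects = set(split.group_subjects(g))
        test_mask = np.isin(dataset.subject_ids, list(test_subjects))
        train, test = dataset.subset(~test_mask), dataset.subset(test_mask)
        assert not (set(train.subjects()) & set(test.subjects())), \
            "subject leakage between train and test folds"
        yield g, train, test


def _resolve_augmenters(augmenter_name, cfg: RunConfig, seed: int):
    """Return a list of (label, augmenter-or-None); DTF expands to three."""
    if isinstance(augmenter_name, BaseAugmenter):
        return [(augmenter_name.name, augmenter_name)]
    if augmenter_name == "DTF":
        return [(m, get_augmenter(m, cfg, rng_seed=seed)) for m in DTF_MEMBERS]
    return [(augmenter_name, get_augmenter(augmenter_name, cfg, rng_seed=seed))]


def _mean_metrics(fold_metrics: list[dict]) -> dict:
    return {k: float(np.mean([m[k] for m in fold_metrics])) for k in METRIC_KEYS}


def _run_cv(dataset: WindowDataset, augmenter_name, cfg: RunConfig,
            synthetic_only: bool, plan_fn=None) -> dict:
    """Shared LOGO-CV engine for the mixed and TSTR protocols.

    ``plan_fn(n_adl, n_fall) -> (n_synth_fall, n_synth_adl)`` overrides the
    balancing plan (used by the ratio sweep); None means the default plan.
    """
    split = make_logo_splits(dataset.subjects(), n_groups=cfg.n_groups)
    per_fold = []
    for g, train_raw, test_raw in _iter_folds(dataset, split):
        fold_seed = child_seed(cfg.seed, f"fold{g}")
        train_raw = subsample_stratified(train_raw, cfg.real_fraction,
                                         child_seed(fold_seed, "subsample"))
        counts = train_raw.class_counts()
        if min(counts.values()) == 0:
            warnings.warn(f"fold {g}: single-class training data; fold skipped")
            continue
        norm = fit_normalization(train_raw, fit_scope=f"fold{g}-train")
        train = norm.transform_dataset(train_raw)
        test = norm.transform_dataset(test_raw)

        members = _resolve_augmenters(augmenter_name, cfg,
                                      child_seed(fold_seed, "augmenter"))
        member_metrics = []
        for m_name, augmenter in members:
            if augmenter is None:  # baseline: real data only
                train_full = train
            else:
                augmenter = clone(augmenter)
                augmenter.fit(train)
                if plan_fn is None:
                    plan = compute_plan(counts["ADL"], counts["FALL"])
                    n_sf, n_sa = plan.n_synth_fall, plan.n_synth_adl
                else:
                    n_sf, n_sa = plan_fn(counts["ADL"], counts["FALL"])
                synth = augmenter.sample(n_sf, n_sa,
                                         seed=child_seed(fold_seed, f"sample-{m_name}"))
                train_full = synth if synthetic_only else \
                    WindowDataset.concat([train, synth])
            det = CNNFallDetector(hyper=cfg.detector, dropout=cfg.dropout,
                                  fc_hidden=cfg.fc_hidden,
                                  seed=child_seed(fold_seed, f"detector-{m_name}"))
            det.fit(train_full.values, train_full.labels)
            metrics = evaluate_detector(det, test)
            metrics["member"] = m_name
            metrics["n_train_real"] = 0 if (synthetic_only and augmenter is not None) \
                else len(train)
            metrics["n_train_synth"] = 0 if augmenter is None else len(train_full) - \
                (0 if synthetic_only else len(train))
            member_metrics.append(metrics)
        fold = {k: float(np.mean([m[k] for m in member_metrics])) for k in METRIC_KEYS}
        fold["fold"] = g
        fold["members"] = member_metrics
        fold["class_counts"] = counts
        per_fold.append(fold)
    if not per_fold:
        raise ValueError("no usable folds (all single-class)")
    return {"augmenter": augmenter_name if isinstance(augmenter_name, str)
            else augmenter_name.name,
            "per_fold": per_fold, "mean": _mean_metrics(per_fold)}


def run_fall_detection_cv(dataset: WindowDataset, augmenter_name,
                          cfg: RunConfig) -> dict:
    """LOGO-CV with the detector trained on real + synthetic windows."""
    return _run_cv(dataset, augmenter_name, cfg, synthetic_only=False)


def run_tstr(dataset: WindowDataset, augmenter_name, cfg: RunConfig) -> dict:
    """Train-on-synthetic-test-on-real under the same LOGO-CV folds."""
    if augmenter_name == "BL":
        raise ValueError("TSTR needs a generative augmenter, not the baseline")
    return _run_cv(dataset, augmenter_name, cfg, synthetic_only=True)


# ---------------------------------------------------------------------------
# dispersion statistics
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    s_w: float
    s_b: float
    ratio: float
    priors: dict = field(default_factory=dict)
    class_sizes: dict = field(default_factory=dict)
    n_classes: int = 0
    infinite: bool = False


def dispersion(groups: list[tuple[str, np.ndarray]]) -> DispersionResult:
    """Prior-weighted within/between scatter of labelled window groups.

    ``groups`` is a list of (label, (n_i, ...) array); arrays are
    flattened per sample.  Scatter matrices are scalarized as
    trace / dimension so values are comparable across feature sizes.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    flat = []
    for label, vals in groups:
        v = np.asarray(vals, dtype=float)
        if len(v) == 0:
            raise ValueError(f"group {label!r} is empty")
        flat.append((label, v.reshape(len(v), -1)))
    d = flat[0][1].shape[1]
    n_total = sum(len(v) for _, v in flat)
    priors = {label: len(v) / n_total for label, v in flat}
    means = {label: v.mean(axis=0) for label, v in flat}
    s_w = sum(priors[label] * float(((v - means[label]) ** 2).sum(axis=1).mean()) / d
              for label, v in flat)
    s_b = 0.5 * sum(priors[li] * priors[lj]
                    * float(((means[li] - means[lj]) ** 2).sum()) / d
                    for li, _ in flat for lj, _ in flat)
    if s_w == 0.0:
        return DispersionResult(s_w=0.0, s_b=s_b, ratio=float("inf"),
                                priors=priors,
                                class_sizes={l: len(v) for l, v in flat},
                                n_classes=len(flat), infinite=True)
    return DispersionResult(s_w=s_w, s_b=s_b, ratio=s_b / s_w, priors=priors,
                            class_sizes={l: len(v) for l, v in flat},
                            n_classes=len(flat))


def divergence_report(real: WindowDataset, synthetic: WindowDataset,
                      seed: int = 0) -> dict:
    """The two dispersion comparisons used to score synthetic data quality.

    ``class_separation``: dispersion between synthetic FALL and synthetic
    ADL windows (higher ratio = classes better separated).
    ``realism``: dispersion between real and synthetic windows after
    drawing an equal number of samples per (class x realness) cell
    (lower ratio = synthetic closer to real).
    """
    cells = {}
    for name, ds in (("real", real), ("synthetic", synthetic)):
        for label, lname in ((LABEL_FALL, "fall"), (LABEL_ADL, "adl")):
            v = ds.values[ds.labels == label]
            if len(v) == 0:
                raise ValueError(f"{name} {lname} group is empty")
            cells[(name, lname)] = v
    sep = dispersion([("fall", cells[("synthetic", "fall")]),
                      ("adl", cells[("synthetic", "adl")])])
    m = min(len(v) for v in cells.values())
    # the draw depends only on (class, cell size), so a synthetic set that
    # copies the real one verbatim subsamples identically and scores 0
    sub = {}
    for (name, lname), v in cells.items():
        rng_cell = np.random.default_rng(
            child_seed(seed, f"cell-{lname}-{len(v)}"))
        sub[(name, lname)] = v[rng_cell.choice(len(v), size=m, replace=False)]
    realism = dispersion([
        ("real", np.concatenate([sub[("real", "fall")], sub[("real", "adl")]])),
        ("synthetic", np.concatenate([sub[("synthetic", "fall")],
                                      sub[("synthetic", "adl")]])),
    ])
    return {"class_separation": sep, "realism": realism,
            "samples_per_cell": m}


# ---------------------------------------------------------------------------
# real-to-synthetic ratio sweep
# ---------------------------------------------------------------------------

def sweep_allocation(n_adl: int, n_fall: int, multiplier: float):
    """Per-class synthetic counts for a total budget of multiplier x real.

    The budget is split so the combined set is balanced when feasible;
    otherwise everything goes to the minority (fall) class and the cell
    is flagged infeasible.
    """
    total = int(round(multiplier * (n_adl + n_fall)))
    deficit = n_adl - n_fall
    if total >= deficit:
        n_sf = (total + deficit) // 2
        n_sa = total - n_sf
        return n_sf, n_sa, False
    return total, 0, True


def ratio_sweep(dataset: WindowDataset, augmenter_name, real_fractions,
                synth_multipliers, cfg: RunConfig) -> dict:
    """Grid of mean LOGO-CV F1 over (real fraction, synthetic multiplier)."""
    grid = np.zeros((len(real_fractions), len(synth_multipliers)))
    flags = np.zeros_like(grid, dtype=bool)
    cells = []
    for i, f in enumerate(real_fractions):
        if not (0.0 < f <= 1.0):
            raise ValueError("real fractions must lie in (0, 1]")
        for j, m in enumerate(synth_multipliers):
            if m < 0:
                raise ValueError("synthetic multipliers must be >= 0")
            cfg_cell = clone_config(cfg, real_fraction=f)
            if m == 0 or augmenter_name == "BL":
                res = _run_cv(dataset, "BL", cfg_cell, synthetic_only=False)
                infeasible = False
            else:
                infeasible_flag = []

                def plan_fn(n_adl, n_fall, _m=m, _flag=infeasible_flag):
                    n_sf, n_sa, bad = sweep_allocation(n_adl, n_fall, _m)
                    if bad:
                        _flag.append(True)
                    return n_sf, n_sa

                res = _run_cv(dataset, augmenter_name, cfg_cell,
                              synthetic_only=False, plan_fn=plan_fn)
                infeasible = bool(infeasible_flag)
            grid[i, j] = res["mean"]["f1"]
            flags[i, j] = infeasible
            cells.append({"real_fraction": f, "multiplier": m,
                          "mean": res["mean"], "infeasible": infeasible})
    return {"real_fractions": list(real_fractions),
            "synth_multipliers": list(synth_multipliers),
            "f1_grid": grid, "infeasible": flags, "cells": cells}


def clone_config(cfg: RunConfig, **overrides) -> RunConfig:
    data = dict(cfg.__dict__)
    data.update(overrides)
    return RunConfig(**data)
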