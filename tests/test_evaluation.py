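"""LOGO-CV protocol, dispersion statistics, TSTR and the ratio sweep."""

import numpy as np
import pytest

from fallaug.augment import BaseAugmenter
from fallaug.config import RunConfig, TrainHyper
from fallaug.data import LABEL_ADL, LABEL_FALL, WindowDataset
from fallaug.evaluation import (dispersion, divergence_report, make_logo_splits,
                                ratio_sweep, run_fall_detection_cv, run_tstr,
                                subsample_stratified, sweep_allocation)


class TestLogoSplits:
    def test_seventeen_subjects_give_4_4_4_5(self):
        split = make_logo_splits(range(1, 18), n_groups=4)
        sizes = sorted(len(split.group_subjects(g)) for g in range(4))
        assert sizes == [4, 4, 4, 5]
        # larger group last
        assert len(split.group_subjects(3)) == 5

    def test_four_subjects_one_each(self):
        split = make_logo_splits([3, 1, 4, 2], n_groups=4)
        assert all(len(split.group_subjects(g)) == 1 for g in range(4))

    def test_partition_covers_all_subjects_without_overlap(self):
        subjects = list(range(1, 18))
        split = make_logo_splits(subjects, n_groups=4)
        folds = [set(split.group_subjects(g)) for g in range(4)]
        assert set().union(*folds) == set(subjects)
        assert sum(len(f) for f in folds) == len(subjects)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError, match="cannot fill"):
            make_logo_splits([1, 2], n_groups=4)


class TestDispersion:
    def test_identical_means_give_zero_between_scatter(self, rng):
        a = rng.normal(size=(40, 5))
        b = a + 0.0
        res = dispersion([("a", a), ("b", b)])
        assert res.s_b == pytest.approx(0.0, abs=1e-18)
        assert res.ratio == pytest.approx(0.0, abs=1e-15)

    def test_one_dimensional_hand_example(self):
        # class A = {0, 2}, class B = {10, 12}: means 1 and 11, equal priors
        # S_W = 0.5*1 + 0.5*1 = 1; S_B = 0.5 * (2 * 0.25 * 100) = 25
        res = dispersion([("A", np.array([[0.0], [2.0]])),
                          ("B", np.array([[10.0], [12.0]]))])
        assert res.s_w == pytest.approx(1.0)
        assert res.s_b == pytest.approx(25.0)
        assert res.ratio == pytest.approx(25.0)

    def test_matches_brute_force_double_loop(self, rng):
        groups = [(str(i), rng.normal(size=(rng.integers(3, 9), 3)))
                  for i in range(3)]
        res = dispersion(groups)
        d = 3
        n = sum(len(v) for _, v in groups)
        s_w = 0.0
        for _, v in groups:
            m = v.mean(axis=0)
            s_wi = sum(float((x - m) @ (x - m)) for x in v) / len(v) / d
            s_w += (len(v) / n) * s_wi
        s_b = 0.0
        for _, vi in groups:
            for _, vj in groups:
                mi, mj = vi.mean(axis=0), vj.mean(axis=0)
                s_b += 0.5 * (len(vi) / n) * (len(vj) / n) \
                    * float((mi - mj) @ (mi - mj)) / d
        assert res.s_w == pytest.approx(s_w, rel=1e-10)
        assert res.s_b == pytest.approx(s_b, rel=1e-10)

    def test_ratio_is_scale_invariant(self, rng):
        groups = [("a", rng.normal(size=(10, 4))),
                  ("b", rng.normal(1.0, 1.0, size=(12, 4)))]
        base = dispersion(groups)
        scaled = dispersion([(l, 3.7 * v) for l, v in groups])
        assert scaled.s_w == pytest.approx(3.7**2 * base.s_w)
        assert scaled.s_b == pytest.approx(3.7**2 * base.s_b)
        assert scaled.ratio == pytest.approx(base.ratio)

    def test_degenerate_within_scatter_flags_infinite(self):
        res = dispersion([("a", np.ones((3, 2))), ("b", np.zeros((3, 2)))])
        assert res.infinite and np.isinf(res.ratio)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            dispersion([("a", np.ones((2, 2))), ("b", np.ones((0, 2)))])


def _window_ds(rng, n_fall, n_adl, subjects=(1, 2, 3, 4), offset=0.0,
               provenance="real"):
    n = n_fall + n_adl
    vals = rng.normal(offset, 0.3, size=(n, 6, 100))
    vals[:n_fall] += 0.5  # falls louder
    labels = np.r_[np.ones(n_fall, dtype=int), np.zeros(n_adl, dtype=int)]
    subj = np.array([subjects[i % len(subjects)] for i in range(n)])
    return WindowDataset(np.clip(vals, -1, 1), labels, subj,
                         np.array([provenance] * n, dtype=object))


class TestDivergenceReport:
    def test_copy_of_real_has_zero_realism_ratio(self, rng):
        real = _window_ds(rng, 20, 30)
        synth = WindowDataset(real.values.copy(), real.labels.copy(),
                              real.subject_ids.copy(),
                              np.array(["synthetic/DM"] * len(real), dtype=object))
        rep = divergence_report(real, synth, seed=0)
        assert rep["realism"].ratio == pytest.approx(0.0, abs=1e-12)

    def test_mean_shift_increases_realism_ratio(self, rng):
        real = _window_ds(rng, 20, 30)
        shifted = WindowDataset(np.clip(real.values + 0.4, -1, 1),
                                real.labels.copy(), real.subject_ids.copy(),
                                np.array(["synthetic/DM"] * len(real), dtype=object))
        copy = WindowDataset(real.values.copy(), real.labels.copy(),
                             real.subject_ids.copy(),
                             np.array(["synthetic/DM"] * len(real), dtype=object))
        r_copy = divergence_report(real, copy, seed=0)["realism"].ratio
        r_shift = divergence_report(real, shifted, seed=0)["realism"].ratio
        assert r_shift > r_copy

    def test_reproducible_given_seed(self, rng):
        real = _window_ds(rng, 15, 25)
        synth = _window_ds(rng, 10, 20, provenance="synthetic/DM")
        a = divergence_report(real, synth, seed=3)
        b = divergence_report(real, synth, seed=3)
        assert a["realism"].ratio == b["realism"].ratio
        assert a["class_separation"].ratio == b["class_separation"].ratio

    def test_empty_cell_raises(self, rng):
        real = _window_ds(rng, 10, 10)
        synth = _window_ds(rng, 0, 10, provenance="synthetic/DM")
        with pytest.raises(ValueError, match="empty"):
            divergence_report(real, synth, seed=0)


class TestSubsampling:
    def test_exact_per_class_counts(self, tiny_cohort):
        sub = subsample_stratified(tiny_cohort, 0.25, seed=3)
        full = tiny_cohort.class_counts()
        got = sub.class_counts()
        assert got["ADL"] == round(0.25 * full["ADL"])
        assert got["FALL"] == round(0.25 * full["FALL"])

    def test_subjects_remain_represented(self, tiny_cohort):
        sub = subsample_stratified(tiny_cohort, 0.25, seed=3)
        assert set(sub.subjects()) == set(tiny_cohort.subjects())

    def test_fraction_one_is_identity(self, tiny_cohort):
        assert subsample_stratified(tiny_cohort, 1.0, seed=0) is tiny_cohort


def _fast_cfg(seed=0, **kw):
    cfg = RunConfig(seed=seed, **kw)
    cfg.detector = TrainHyper(epochs=3, batch_size=32)
    return cfg


class TestCVProtocol:
    def test_baseline_beats_chance_on_separable_cohort(self, tiny_cohort):
        cfg = _fast_cfg(seed=1)
        cfg.detector = TrainHyper(epochs=25, batch_size=32)
        res = run_fall_detection_cv(tiny_cohort, "BL", cfg)
        assert res["mean"]["accuracy"] > 0.9
        assert len(res["per_fold"]) == 4

    def test_augmented_fold_training_sets_are_balanced(self, tiny_cohort):
        cfg = _fast_cfg(seed=2)
        res = run_fall_detection_cv(tiny_cohort, "SMOTE", cfg)
        for fold in res["per_fold"]:
            counts = fold["class_counts"]
            member = fold["members"][0]
            # synthetic total equals real total, combined set balanced
            assert member["n_train_synth"] == counts["ADL"] + counts["FALL"]

    def test_tstr_uses_only_synthetic_training_windows(self, tiny_cohort):
        cfg = _fast_cfg(seed=3)
        res = run_tstr(tiny_cohort, "SMOTE", cfg)
        for fold in res["per_fold"]:
            member = fold["members"][0]
            assert member["n_train_real"] == 0
            counts = fold["class_counts"]
            assert member["n_train_synth"] == counts["ADL"] + counts["FALL"]

    def test_tstr_rejects_baseline(self, tiny_cohort):
        with pytest.raises(ValueError, match="baseline"):
            run_tstr(tiny_cohort, "BL", _fast_cfg())

    def test_transform_tstr_tracks_real_trained_baseline(self, tiny_cohort):
        cfg = _fast_cfg(seed=4)
        cfg.detector = TrainHyper(epochs=25, batch_size=32)
        base = run_fall_detection_cv(tiny_cohort, "BL", cfg)
        tstr = run_tstr(tiny_cohort, "rotation", cfg)
        assert abs(tstr["mean"]["accuracy"] - base["mean"]["accuracy"]) < 0.15

    def test_degenerate_constant_generator_scores_near_majority_rate(
            self, tiny_cohort):
        class ConstantAugmenter(BaseAugmenter):
            name = "constant"
            clip_output = False

            def fit(self, dataset, y=None):
                return self

            def sample(self, n_fall, n_adl, seed=0):
                vals = np.zeros((n_fall + n_adl, 6, 100))
                vals[:n_fall] += 1e-3  # tiny offset, both classes ~constant
                labels = np.r_[np.ones(n_fall, dtype=int),
                               np.zeros(n_adl, dtype=int)]
                return WindowDataset(vals, labels,
                                     np.full(len(vals), -1, dtype=int),
                                     np.array(["synthetic/constant"]
                                              * len(vals), dtype=object))

        cfg = _fast_cfg(seed=5)
        cfg.detector = TrainHyper(epochs=10, batch_size=32)
        res = run_tstr(tiny_cohort, ConstantAugmenter(), cfg)
        majority = 1.0 - tiny_cohort.class_counts()["FALL"] / len(tiny_cohort)
        assert abs(res["mean"]["accuracy"] - majority) < 0.2


class TestRatioSweep:
    def test_worked_allocation_example(self):
        # 100 real windows at 50 % -> 50 real; 200 % synthetic -> 100 more,
        # 150 training windows in total
        n_sf, n_sa, flag = sweep_allocation(30, 20, 2.0)
        assert n_sf + n_sa == 100 and not flag
        assert 20 + n_sf == 30 + n_sa  # balanced combined set

    def test_infeasible_budget_goes_to_minority(self):
        n_sf, n_sa, flag = sweep_allocation(100, 10, 0.2)
        assert flag and n_sa == 0 and n_sf == 22

    def test_zero_multiplier_reduces_to_baseline(self, tiny_cohort):
        cfg = _fast_cfg(seed=6)
        grid = ratio_sweep(tiny_cohort, "SMOTE", [0.5], [0.0], cfg)
        base = run_fall_detection_cv(
            tiny_cohort, "BL",
            _fast_cfg(seed=6, real_fraction=0.5))
        assert grid["f1_grid"][0, 0] == pytest.approx(base["mean"]["f1"])

    def test_grid_shape_and_ordering(self, tiny_cohort):
        cfg = _fast_cfg(seed=7)
        res = ratio_sweep(tiny_cohort, "SMOTE", [1.0, 0.5], [0.0, 1.0], cfg)
        assert res["f1_grid"].shape == (2, 2)
        assert res["real_fractions"] == [1.0, 0.5]
        assert res["synth_multipliers"] == [0.0, 1.0]

    def test_invalid_inputs_raise(self, tiny_cohort):
        with pytest.raises(ValueError, match="fractions"):
            ratio_sweep(tiny_cohort, "SMOTE", [0.0], [1.0], _fast_cfg())
        with pytest.raises(ValueError, match="multipliers"):
            ratio_sweep(tiny_cohort, "SMOTE", [0.5], [-1.0], _fast_cfg())


def test_no_subject_leakage_between_folds(tiny_cohort):
    from fallaug.evaluation import _iter_folds
    split = make_logo_splits(tiny_cohort.subjects(), n_groups=4)
    seen = set()
    for g, train, test in _iter_folds(tiny_cohort, split):
        assert not (set(train.subjects()) & set(test.subjects()))
        seen |= set(test.subjects())
    assert seen == set(tiny_cohort.subjects())
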