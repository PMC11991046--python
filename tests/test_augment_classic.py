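"""Balancing plan, signal transforms and SMOTE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallaug.augment import AugmentationPlan, compute_plan
from fallaug.augment.classic import (PermutationAugmenter, RotationAugmenter,
                                     ScalingAugmenter, SmoteAugmenter,
                                     permute_window, rotate_window,
                                     scale_window, smote_generate)
from fallaug.data import WindowDataset


class TestPlan:
    def test_study_scale_counts(self):
        plan = compute_plan(2282, 756)
        assert (plan.n_synth_fall, plan.n_synth_adl) == (2282, 756)

    @pytest.mark.parametrize("adl,fall,expected", [
        (10, 10, (10, 10)), (5, 0, (5, 0))])
    def test_boundary_cases(self, adl, fall, expected):
        plan = compute_plan(adl, fall)
        assert (plan.n_synth_fall, plan.n_synth_adl) == expected

    def test_minority_violation_raises(self):
        with pytest.raises(ValueError, match="minority"):
            compute_plan(5, 9)

    @given(adl=st.integers(0, 10_000), fall=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_both_balance_constraints_hold(self, adl, fall):
        if fall > adl:
            with pytest.raises(ValueError):
                compute_plan(adl, fall)
            return
        plan = compute_plan(adl, fall)
        # total synthetic equals total real; combined classes balanced
        assert plan.total == adl + fall
        assert fall + plan.n_synth_fall == adl + plan.n_synth_adl


class TestRotation:
    def test_identity_rotation_hook(self, rng):
        w = rng.normal(size=(6, 100))
        out = rotate_window(w, rotations=(np.eye(3), np.eye(3)))
        np.testing.assert_array_equal(out, w)

    def test_preserves_per_sample_triplet_norms(self, rng):
        w = rng.normal(size=(6, 100))
        out = rotate_window(w, seed=3)
        for sl in (slice(0, 3), slice(3, 6)):
            np.testing.assert_allclose(np.linalg.norm(out[sl], axis=0),
                                       np.linalg.norm(w[sl], axis=0),
                                       rtol=1e-6)

    def test_known_z_rotation_maps_x_to_y(self):
        w = np.zeros((6, 100)); w[0] = 1.0  # accel x = 1
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = rotate_window(w, rotations=(rz, np.eye(3)))
        np.testing.assert_allclose(out[1], 1.0, atol=1e-12)
        np.testing.assert_allclose(out[0], 0.0, atol=1e-12)

    def test_accel_and_gyro_rotations_are_independent(self, rng):
        w = rng.normal(size=(6, 100))
        out = rotate_window(w, seed=5)
        # gyro part must generally differ from what the accel rotation
        # would have produced
        assert not np.allclose(out[3:], w[3:])


class TestScaling:
    def test_hooks(self, rng):
        w = rng.normal(size=(6, 100))
        np.testing.assert_array_equal(scale_window(w, factor=1.0), w)
        assert (scale_window(w, factor=0.0) == 0).all()
        np.testing.assert_allclose(scale_window(np.ones((6, 100)), factor=0.5), 0.5)

    def test_random_factor_in_range_and_shared(self, rng):
        w = rng.normal(size=(6, 100))
        out = scale_window(w, seed=11)
        factors = out[w != 0] / w[w != 0]
        assert np.allclose(factors, factors[0])
        assert 0.0 <= factors[0] < 2.0


class TestPermutation:
    def test_identity_hook(self, rng):
        w = rng.normal(size=(6, 100))
        np.testing.assert_array_equal(
            permute_window(w, order=np.arange(4)), w)

    def test_labeled_blocks_follow_order(self):
        w = np.concatenate([np.full((6, 25), v) for v in (1, 2, 3, 4)], axis=1)
        out = permute_window(w, order=np.array([1, 0, 3, 2]))
        assert list(out[0, ::25]) == [2, 1, 4, 3]

    def test_sample_multiset_preserved(self, rng):
        w = rng.normal(size=(6, 100))
        out = permute_window(w, seed=8)
        np.testing.assert_allclose(np.sort(out, axis=1), np.sort(w, axis=1))

    def test_indivisible_length_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            permute_window(np.zeros((6, 100)), n_parts=3)


class TestSmote:
    def test_delta_endpoints(self, rng):
        vals = rng.normal(size=(8, 6, 100))
        out0 = smote_generate(vals, 4, k=2, seed=1, delta=0.0)
        # delta=0 reproduces the cycled base samples exactly
        np.testing.assert_array_equal(out0, vals[:4])
        out1 = smote_generate(vals, 8, k=2, seed=1, delta=1.0)
        flat = vals.reshape(8, -1)
        # delta=1 lands exactly on some other class member
        for o in out1.reshape(8, -1):
            assert any(np.allclose(o, f) for f in flat)

    def test_one_dimensional_toy_matches_brute_force(self):
        # class {0, 1, 10} embedded in constant windows; nearest neighbour
        # of 0 is 1, so delta=0.5 must give 0.5
        vals = np.stack([np.full((6, 100), v) for v in (0.0, 1.0, 10.0)])
        out = smote_generate(vals, 1, k=1, seed=0, delta=0.5)
        np.testing.assert_allclose(out[0], 0.5)

    def test_outputs_lie_between_parents_componentwise(self, rng):
        vals = rng.normal(size=(10, 6, 100))
        out = smote_generate(vals, 30, k=3, seed=5)
        flat = vals.reshape(10, -1)
        for j, o in enumerate(out.reshape(30, -1)):
            base = flat[j % 10]
            # find the parent: the unique neighbour consistent with the line
            ok = False
            for other in flat:
                lo = np.minimum(base, other) - 1e-9
                hi = np.maximum(base, other) + 1e-9
                if ((o >= lo) & (o <= hi)).all():
                    ok = True
                    break
            assert ok

    def test_class_smaller_than_k_raises(self, rng):
        with pytest.raises(ValueError, match="k="):
            smote_generate(rng.normal(size=(4, 6, 100)), 2, k=5)

    def test_determinism(self, rng):
        vals = rng.normal(size=(9, 6, 100))
        a = smote_generate(vals, 5, k=2, seed=42)
        b = smote_generate(vals, 5, k=2, seed=42)
        np.testing.assert_array_equal(a, b)


def _train_ds(rng, n_fall=12, n_adl=20):
    vals = rng.normal(size=(n_fall + n_adl, 6, 100))
    labels = np.r_[np.ones(n_fall, dtype=int), np.zeros(n_adl, dtype=int)]
    return WindowDataset(vals, labels, np.ones(len(vals), dtype=int),
                         np.array(["real"] * len(vals), dtype=object))


@pytest.mark.parametrize("cls", [RotationAugmenter, ScalingAugmenter,
                                 PermutationAugmenter, SmoteAugmenter])
def test_augmenters_deliver_exact_plan_counts(cls, rng):
    ds = _train_ds(rng)
    plan = compute_plan(20, 12)
    aug = cls().fit(ds)
    synth = aug.sample_plan(plan, seed=3)
    counts = synth.class_counts()
    assert counts == {"ADL": 12, "FALL": 20}
    assert synth.values.shape[1:] == (6, 100)
    assert all(p.startswith("synthetic/") for p in synth.provenance)
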