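"""Diffusion schedule, forward process, U-Net and conditional sampling."""

import numpy as np
import pytest

from fallaug.augment.diffusion import (DDPM, UNet1d, forward_noise,
                                       make_schedule, sinusoidal_embedding)
from fallaug.config import TrainHyper


class TestSchedule:
    def test_single_step(self):
        s = make_schedule(T=1, beta_start=1e-4, beta_end=1e-4)
        np.testing.assert_allclose(s.alpha_bar, [1 - 1e-4])

    def test_default_schedule_decreasing_with_tiny_tail(self):
        s = make_schedule()
        assert s.T == 1000
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert s.alpha_bar[-1] < 0.01
        assert np.all((s.beta > 0) & (s.beta < 1))

    def test_constant_beta_closed_form(self):
        c = 0.05
        s = make_schedule(T=20, beta_start=c, beta_end=c)
        np.testing.assert_allclose(s.alpha_bar, (1 - c) ** np.arange(1, 21),
                                   rtol=1e-12)

    def test_invalid_endpoints_raise(self):
        with pytest.raises(ValueError):
            make_schedule(beta_start=0.0)
        with pytest.raises(ValueError):
            make_schedule(beta_start=0.5, beta_end=0.1)


class TestForwardNoise:
    def test_near_identity_at_first_step(self, rng):
        s = make_schedule(T=10, beta_start=1e-8, beta_end=1e-8)
        x0 = rng.normal(size=(2, 6, 100))
        noise = rng.normal(size=x0.shape)
        np.testing.assert_allclose(forward_noise(x0, 1, s, noise), x0, atol=1e-3)

    def test_zero_signal_leaves_scaled_noise(self, rng):
        s = make_schedule(T=100, beta_start=1e-4, beta_end=0.1)
        noise = rng.normal(size=(1, 6, 100))
        out = forward_noise(np.zeros((1, 6, 100)), 40, s, noise)
        np.testing.assert_allclose(out, np.sqrt(1 - s.alpha_bar[39]) * noise)

    def test_out_of_range_timestep_raises(self, rng):
        s = make_schedule(T=10, beta_start=1e-3, beta_end=1e-2)
        with pytest.raises(ValueError, match="t must be"):
            forward_noise(np.zeros((1, 6, 100)), 11, s, np.zeros((1, 6, 100)))

    def test_closed_form_jump_matches_iterated_markov_steps(self):
        """Monte-Carlo oracle: three iterated single steps vs the jump.

        Per element, both constructions give mean sqrt(alpha_bar_3) x0 and
        variance 1 - alpha_bar_3; means and variances must agree within
        three standard errors over 10 000 draws.
        """
        s = make_schedule(T=3, beta_start=0.05, beta_end=0.3)
        rng_mc = np.random.default_rng(123)
        x0 = 0.7
        n = 10_000
        iterated = np.full(n, x0)
        for t in range(3):
            iterated = (np.sqrt(1 - s.beta[t]) * iterated
                        + np.sqrt(s.beta[t]) * rng_mc.normal(size=n))
        jump = forward_noise(np.full(n, x0), 3, s, rng_mc.normal(size=n))
        for sample in (iterated, jump):
            se_mean = sample.std() / np.sqrt(n)
            assert abs(sample.mean() - np.sqrt(s.alpha_bar[2]) * x0) < 3 * se_mean
            target_var = 1 - s.alpha_bar[2]
            se_var = sample.var() * np.sqrt(2 / (n - 1))
            assert abs(sample.var() - target_var) < 3 * se_var
        assert abs(iterated.mean() - jump.mean()) < 3 * np.sqrt(
            iterated.var() / n + jump.var() / n)


class TestUNet:
    @pytest.mark.parametrize("t", [1, 50, 100])
    def test_forward_finite_and_shape_preserving(self, t):
        net = UNet1d(width=16, rng=np.random.default_rng(0))
        out = net.forward(np.zeros((2, 6, 100), dtype=np.float32), t, [0, 1])
        assert out.shape == (2, 6, 100)
        assert np.isfinite(out).all()

    def test_sinusoidal_embedding_shape_and_range(self):
        emb = sinusoidal_embedding(np.array([1, 500, 1000]), 64)
        assert emb.shape == (3, 64)
        assert np.abs(emb).max() <= 1.0
        assert not np.allclose(emb[0], emb[2])


@pytest.fixture(scope="module")
def toy_training_set():
    rng = np.random.default_rng(9)
    vals = np.clip(rng.normal(0, 0.3, size=(64, 6, 100)), -1, 1)
    labels = rng.integers(0, 2, size=64)
    return vals, labels


class TestTraining:
    def test_initial_loss_near_unit_variance(self, toy_training_set):
        # an uninformative predictor of standard normal noise has expected
        # MSE equal to the noise variance; the zero-initialized output
        # layer realises that at step one
        vals, labels = toy_training_set
        model = DDPM(make_schedule(T=100, beta_end=0.1), width=16, seed=0)
        history = model.train_epochs(vals, labels,
                                     TrainHyper(epochs=1, batch_size=64))
        assert abs(history[0] - 1.0) < 0.2

    def test_loss_decreases_with_training(self, toy_training_set):
        vals, labels = toy_training_set
        model = DDPM(make_schedule(T=100, beta_end=0.1), width=16, seed=0)
        history = model.train_epochs(vals, labels,
                                     TrainHyper(lr=1e-3, epochs=30, batch_size=32))
        assert np.mean(history[-3:]) < np.mean(history[:3])

    def test_empty_dataset_raises(self):
        model = DDPM(make_schedule(T=10, beta_end=0.1), width=16, seed=0)
        with pytest.raises(ValueError, match="empty"):
            model.train_epochs(np.zeros((0, 6, 100)), np.zeros(0, dtype=int),
                               TrainHyper(epochs=1))

    def test_model_output_shape_contract(self, toy_training_set):
        vals, labels = toy_training_set
        model = DDPM(make_schedule(T=100, beta_end=0.1), width=16, seed=0)
        out = model.predict_noise(vals[:3], 10, labels[:3])
        assert out.shape == (3, 6, 100)


class TestSampling:
    def test_zero_count(self):
        model = DDPM(make_schedule(T=10, beta_end=0.1), width=16, seed=0)
        assert model.sample(0, 1).shape == (0, 6, 100)

    def test_fixed_seed_is_bit_identical(self, toy_training_set):
        vals, labels = toy_training_set
        model = DDPM(make_schedule(T=20, beta_end=0.3), width=16, seed=0)
        model.train_epochs(vals, labels, TrainHyper(epochs=2, batch_size=64))
        a = model.sample(3, 1, seed=5)
        b = model.sample(3, 1, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= -1.0 and a.max() <= 1.0
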