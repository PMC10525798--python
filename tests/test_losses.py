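import math
from itertools import permutations

import autograd.numpy as anp
import numpy as np
import pytest

from adverseg.critic import CriticConfig, build_critic
from adverseg.errors import ShapeError, ValidationError
from adverseg.training import (
    _gp_value,
    _interpolates,
    adv_losses_gan,
    critic_loss_wgan,
    generator_adv_loss,
    gradient_penalty,
    one_hot,
    segmentation_loss,
    wasserstein_1d,
    wasserstein_1d_bruteforce,
)


class LinearCritic:
    """Single fully connected layer, no nonlinearity — closed-form gradients."""

    def __init__(self, w, b=0.0):
        self.w, self.b = np.asarray(w, dtype=np.float64), b
        self.params = self.w

    def make_input(self, image, mask):
        image = np.asarray(image)
        if image.ndim == 3:
            image = image[..., None]
        return anp.concatenate([image, mask], axis=-1)

    def score_input(self, params, x):
        return anp.reshape(x, (x.shape[0], -1)) @ params + self.b


class TestWganLosses:
    def test_symmetric_zero(self):
        assert critic_loss_wgan([1.0, 2.0], [1.0, 2.0], 0.0, 10.0) == 0.0

    def test_exact_arithmetic(self):
        assert critic_loss_wgan([1.0, 1.0], [0.0, 0.0], 0.0, 10.0) == -1.0

    def test_brute_force_oracle(self, rng):
        real = rng.standard_normal(64)
        fake = rng.standard_normal(64)
        gp = float(rng.random())
        lam = 10.0
        # independent mean computation
        expected = sum(fake) / 64 - sum(real) / 64 + lam * gp
        assert critic_loss_wgan(real, fake, gp, lam) == pytest.approx(expected, abs=1e-12)

    def test_generator_loss(self):
        assert generator_adv_loss([0.0, 0.0]) == 0.0
        assert generator_adv_loss([2.0, 4.0]) == -3.0

    def test_generator_loss_monotone(self, rng):
        s = rng.standard_normal(16)
        assert generator_adv_loss(s + 0.5) < generator_adv_loss(s)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            critic_loss_wgan([], [1.0], 0.0, 1.0)
        with pytest.raises(ValidationError):
            generator_adv_loss([])


class TestGanLosses:
    def test_zero_logits(self):
        g, d = adv_losses_gan([0.0, 0.0], [0.0, 0.0])
        assert d == pytest.approx(2 * math.log(2), abs=1e-12)
        assert g == pytest.approx(math.log(2), abs=1e-12)

    def test_generator_limit(self):
        g, _ = adv_losses_gan([50.0, 60.0], [0.0])
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_scalar_oracle(self, rng):
        fake = rng.standard_normal(32)
        real = rng.standard_normal(32)
        sig = lambda x: 1.0 / (1.0 + math.exp(-x))
        d_exp = -np.mean([math.log(sig(x)) for x in real]) - np.mean(
            [math.log(1 - sig(x)) for x in fake]
        )
        g_exp = -np.mean([math.log(sig(x)) for x in fake])
        g, d = adv_losses_gan(fake, real)
        assert d == pytest.approx(d_exp, abs=1e-12)
        assert g == pytest.approx(g_exp, abs=1e-12)


class TestGradientPenalty:
    def _pairs(self, rng, h=8):
        img = rng.random((3, h, h))
        real = one_hot(rng.integers(0, 4, (3, h, h)), 4)
        fake = rng.dirichlet(np.ones(4), (3, h, h))
        return (img, real), (img, fake)

    def test_unit_norm_linear_critic_zero(self, rng):
        real, fake = self._pairs(rng)
        w = rng.standard_normal(8 * 8 * 5)
        w /= np.linalg.norm(w)
        assert gradient_penalty(LinearCritic(w), real, fake, seed=1) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_norm_three_linear_critic(self, rng):
        real, fake = self._pairs(rng)
        w = rng.standard_normal(8 * 8 * 5)
        w *= 3.0 / np.linalg.norm(w)
        assert gradient_penalty(LinearCritic(w), real, fake, seed=1) == pytest.approx(
            4.0, abs=1e-6
        )

    def test_finite_difference_oracle(self, rng):
        """Central-difference gradient-norm oracle on ≤10³ input elements."""
        cfg = CriticConfig(
            in_channels=5, base_filters=2, stages=1, input_side=8, norm_kind="none"
        )
        c = build_critic(cfg, seed=3)
        real, fake = self._pairs(rng)
        real_in = np.asarray(c.make_input(*real))
        fake_in = np.asarray(c.make_input(*fake))
        xhat = _interpolates(real_in, fake_in, np.random.default_rng(5))
        gp_auto = float(_gp_value(c, c.params, xhat))

        eps = 1e-5
        score = lambda x: np.asarray(c.score_input(c.params, x))
        gnum = np.zeros_like(xhat)
        for idx in np.ndindex(*xhat.shape):
            xp = xhat.copy()
            xp[idx] += eps
            xm = xhat.copy()
            xm[idx] -= eps
            gnum[idx] = (score(xp)[idx[0]] - score(xm)[idx[0]]) / (2 * eps)
        norms = np.sqrt((gnum**2).sum(axis=(1, 2, 3)))
        gp_fd = float(np.mean((norms - 1.0) ** 2))
        assert gp_auto == pytest.approx(gp_fd, abs=1e-4)

    def test_nonnegative(self, rng):
        cfg = CriticConfig(in_channels=5, base_filters=2, stages=1, input_side=8)
        c = build_critic(cfg, seed=0)
        real, fake = self._pairs(rng)
        assert gradient_penalty(c, real, fake, seed=2) >= 0.0


class TestSegmentationLoss:
    def test_perfect_prediction(self, rng):
        target = rng.integers(0, 4, (2, 8, 8))
        pred = one_hot(target, 4)
        assert segmentation_loss(pred, target, "dice") == pytest.approx(0.0, abs=1e-5)
        # exact one-hot has log(1)=0 at the target entries
        assert segmentation_loss(pred, target, "ce") == pytest.approx(0.0, abs=1e-10)

    def test_uniform_ce_ln4(self, rng):
        target = rng.integers(0, 4, (2, 8, 8))
        pred = np.full((2, 8, 8, 4), 0.25)
        assert segmentation_loss(pred, target, "ce") == pytest.approx(
            math.log(4), rel=1e-9
        )

    def test_soft_dice_brute_force(self, rng):
        """Σ-based soft-Dice oracle, coded independently."""
        target = rng.integers(0, 4, (2, 6, 6))
        pred = rng.dirichlet(np.ones(4), (2, 6, 6))
        t_oh = one_hot(target, 4)
        smooth = 1e-6
        dices = []
        for lab in range(1, 4):
            num = 2.0 * (pred[..., lab] * t_oh[..., lab]).sum() + smooth
            den = pred[..., lab].sum() + t_oh[..., lab].sum() + smooth
            dices.append(num / den)
        expected = 1.0 - np.mean(dices)
        assert segmentation_loss(pred, target, "dice") == pytest.approx(
            expected, abs=1e-10
        )

    def test_dice_ce_is_sum(self, rng):
        target = rng.integers(0, 4, (1, 8, 8))
        pred = rng.dirichlet(np.ones(4), (1, 8, 8))
        total = segmentation_loss(pred, target, "dice+ce")
        parts = segmentation_loss(pred, target, "dice") + segmentation_loss(
            pred, target, "ce"
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_label_out_of_range(self, rng):
        pred = rng.dirichlet(np.ones(4), (1, 4, 4))
        with pytest.raises(ValidationError):
            segmentation_loss(pred, np.full((1, 4, 4), 9), "ce")

    def test_bad_kind(self, rng):
        pred = rng.dirichlet(np.ones(4), (1, 4, 4))
        with pytest.raises(ValidationError):
            segmentation_loss(pred, np.zeros((1, 4, 4), dtype=int), "focal")


class TestWasserstein1D:
    def test_identical_zero(self, rng):
        a = rng.standard_normal(10)
        assert wasserstein_1d(a, a) == 0.0

    def test_point_mass_shift(self):
        assert wasserstein_1d([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_permutation_oracle(self, rng):
        for n in range(1, 7):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            assert wasserstein_1d(a, b) == pytest.approx(
                wasserstein_1d_bruteforce(a, b), abs=1e-9
            )

    def test_scipy_cross_check(self, rng):
        from scipy.stats import wasserstein_distance

        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        assert wasserstein_1d(a, b) == pytest.approx(
            wasserstein_distance(a, b), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            wasserstein_1d([1.0], [1.0, 2.0])
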