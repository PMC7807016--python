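"""Analytic checks of every loss term and the epoch weight schedule."""

import math

import numpy as np
import pytest

from cycledeblur import autodiff as ad
from cycledeblur import losses as L
from cycledeblur.autodiff import Tensor


class ConstantCritic:
    """D(x) = c for every patch."""

    def __init__(self, c):
        self.c = c

    def __call__(self, t):
        return ad.add(ad.mul(0.0, ad.sum_(t, axis=(2, 3), keepdims=True)), self.c)


class LinearCritic:
    """D(x) = sum(w * x); with w = 1/sqrt(N) the input-gradient norm is 1."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=np.float32)

    def __call__(self, t):
        return ad.sum_(ad.mul(t, Tensor(self.w)), axis=(1, 2, 3), keepdims=True)


class MapGenerator:
    """Generator standing in as a fixed array map or a callable on data."""

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, t):
        return ad.as_tensor(self.fn(ad.as_tensor(t).data))


IDENTITY = MapGenerator(lambda d: d)


class TestCriticLoss:
    def test_constant_critic_gives_exactly_the_penalty_weight(self, rng):
        real = rng.random((4, 1, 8, 8)).astype(np.float32)
        fake = rng.random((4, 1, 8, 8)).astype(np.float32)
        loss = L.wgan_gp_critic_loss(ConstantCritic(3.0), real, fake,
                                     gp_lambda=10.0, seed=0)
        assert loss.item() == pytest.approx(10.0, abs=1e-4)

    def test_unit_gradient_critic_has_zero_penalty(self, rng):
        n = 64
        critic = LinearCritic(np.full((1, 1, 8, 8), 1 / math.sqrt(n)))
        mix = Tensor(rng.random((4, 1, 8, 8)).astype(np.float32),
                     requires_grad=True)
        assert L.gradient_penalty(critic, mix).item() == pytest.approx(0.0, abs=1e-5)

    def test_linear_critic_matches_closed_form(self, rng):
        """2x2 images, linear critic with known weights: the Wasserstein part
        is w . (mean_fake - mean_real) and the penalty has gradient norm
        ||w|| for every mixture."""
        w = np.array([[[[0.5, -1.0], [2.0, 0.25]]]], dtype=np.float32)
        real = rng.random((8, 1, 2, 2)).astype(np.float32)
        fake = rng.random((8, 1, 2, 2)).astype(np.float32)
        critic = LinearCritic(w)
        gp = 10.0
        loss = L.wgan_gp_critic_loss(critic, real, fake, gp_lambda=gp, seed=5)
        wass = float((w * (fake.mean(0) - real.mean(0))).sum())
        wnorm = float(np.sqrt((w ** 2).sum()))
        expected = wass + gp * (wnorm - 1.0) ** 2
        assert loss.item() == pytest.approx(expected, abs=1e-5)

    def test_nonfinite_critic_output_raises(self, rng):
        real = rng.random((2, 1, 4, 4)).astype(np.float32)
        bad = ConstantCritic(np.inf)
        with pytest.raises(FloatingPointError):
            L.wgan_gp_critic_loss(bad, real, real, seed=0)


class TestAdversarialGeneratorLoss:
    def test_zero_critics(self, rng):
        x = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        val = L.adversarial_generator_loss(ConstantCritic(0.0), ConstantCritic(0.0),
                                           x, y, IDENTITY, IDENTITY)
        assert val.item() == pytest.approx(0.0)

    def test_constant_critics_give_minus_two_c(self, rng):
        x = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        val = L.adversarial_generator_loss(ConstantCritic(1.5), ConstantCritic(1.5),
                                           x, y, IDENTITY, IDENTITY)
        assert val.item() == pytest.approx(-3.0)

    def test_matches_independent_score_means(self, rng, tiny_nets):
        x = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        D_F, D_C = tiny_nets["D_F"], tiny_nets["D_C"]
        G_CF, G_FC = tiny_nets["G_CF"], tiny_nets["G_FC"]
        val = L.adversarial_generator_loss(D_F, D_C, x, y, G_CF, G_FC)
        with ad.no_grad():
            s_f = float(np.mean([D_F(G_CF(x)).data[b].mean() for b in range(2)]))
            s_c = float(np.mean([D_C(G_FC(y)).data[b].mean() for b in range(2)]))
        assert val.item() == pytest.approx(-(s_f + s_c), rel=1e-5)


class TestCycleLoss:
    def test_identity_generators_give_zero(self, rng):
        x = Tensor(rng.random((2, 1, 6, 6)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 6, 6)).astype(np.float32))
        assert L.cycle_loss(x, y, IDENTITY, IDENTITY).item() == pytest.approx(
            0.0, abs=1e-5)

    def test_constant_shift_gives_delta(self, rng):
        """A cycle that shifts every pixel by delta scores delta per
        direction (RMS of a constant residual image)."""
        delta = 0.25
        shift = MapGenerator(lambda d: d + delta / 2)  # applied twice: +delta
        x = Tensor(rng.random((3, 1, 6, 6)).astype(np.float32))
        y = Tensor(rng.random((3, 1, 6, 6)).astype(np.float32))
        val = L.cycle_loss(x, y, shift, shift)
        assert val.item() == pytest.approx(2 * delta, rel=1e-4)

    def test_matches_recomputation_with_tiny_nets(self, rng, tiny_nets):
        x = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        G_CF, G_FC = tiny_nets["G_CF"], tiny_nets["G_FC"]
        val = L.cycle_loss(x, y, G_CF, G_FC)
        with ad.no_grad():
            rx = x.data - G_FC(G_CF(x)).data
            ry = y.data - G_CF(G_FC(y)).data
            expected = float(
                np.mean(np.sqrt((rx ** 2).mean(axis=(1, 2, 3)) + 1e-12)) +
                np.mean(np.sqrt((ry ** 2).mean(axis=(1, 2, 3)) + 1e-12)))
        assert val.item() == pytest.approx(expected, rel=1e-5)


class TestGeneratedLoss:
    def test_perfect_translation_gives_zero(self, rng):
        xd = rng.random((2, 1, 4, 4)).astype(np.float32)
        yd = rng.random((2, 1, 4, 4)).astype(np.float32)
        G_CF = MapGenerator(lambda d: yd)
        G_FC = MapGenerator(lambda d: xd)
        val = L.generated_loss(Tensor(xd), Tensor(yd), G_CF, G_FC)
        assert val.item() == 0.0

    def test_constant_residual_gives_two_c(self, rng):
        c = 0.125
        x = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        G_CF = MapGenerator(lambda d: y.data - c)  # |y - G(x)| = c
        G_FC = MapGenerator(lambda d: x.data - c)
        val = L.generated_loss(x, y, G_CF, G_FC)
        assert val.item() == pytest.approx(2 * c, rel=1e-5)

    def test_toy_two_by_two_hand_arithmetic(self):
        x = Tensor(np.array([[[[0.0, 1.0], [1.0, 0.0]]]], dtype=np.float32))
        y = Tensor(np.array([[[[1.0, 0.0], [0.0, 1.0]]]], dtype=np.float32))
        val = L.generated_loss(x, y, IDENTITY, IDENTITY)
        assert val.item() == pytest.approx(2.0)

    def test_unpaired_shapes_rejected(self, rng):
        x = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 6, 6)).astype(np.float32))
        with pytest.raises(ValueError):
            L.generated_loss(x, y, IDENTITY, IDENTITY)


class TestIdentityLoss:
    def test_identity_generators_zero_in_both_modes(self, rng):
        x = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        for mode in ("literal", "classic"):
            val = L.identity_loss(x, y, IDENTITY, IDENTITY, mode=mode)
            assert val.item() == pytest.approx(0.0, abs=1e-4)

    def test_constant_generator_is_a_fixed_point_of_literal_mode(self, rng):
        c = rng.random((1, 1, 4, 4)).astype(np.float32)
        const = MapGenerator(lambda d: np.broadcast_to(c, d.shape).copy())
        x = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 4, 4)).astype(np.float32))
        val = L.identity_loss(x, y, const, const, mode="literal")
        assert val.item() == pytest.approx(0.0, abs=1e-5)

    def test_literal_mode_matches_recomputation(self, rng, tiny_nets):
        x = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        G_CF, G_FC = tiny_nets["G_CF"], tiny_nets["G_FC"]
        val = L.identity_loss(x, y, G_CF, G_FC, mode="literal")
        with ad.no_grad():
            yh = G_CF(x).data
            xh = G_FC(y).data
            r1 = yh - G_CF(Tensor(yh)).data
            r2 = xh - G_FC(Tensor(xh)).data
            expected = float(
                np.mean(np.sqrt((r1 ** 2).mean(axis=(1, 2, 3)) + 1e-12)) +
                np.mean(np.sqrt((r2 ** 2).mean(axis=(1, 2, 3)) + 1e-12)))
        assert val.item() == pytest.approx(expected, rel=1e-5)


class TestSobelLoss:
    def test_zero_residual(self, rng):
        xd = rng.random((1, 1, 8, 8)).astype(np.float32)
        yd = rng.random((1, 1, 8, 8)).astype(np.float32)
        G_CF = MapGenerator(lambda d: yd)
        G_FC = MapGenerator(lambda d: xd)
        assert L.sobel_loss(Tensor(xd), Tensor(yd), G_CF, G_FC).item() == 0.0

    def test_constant_residual_scores_zero(self, rng):
        """Sobel of a constant is zero everywhere thanks to edge-replicate
        padding."""
        x = Tensor(rng.random((1, 1, 8, 8)).astype(np.float32))
        y = Tensor(rng.random((1, 1, 8, 8)).astype(np.float32))
        G_CF = MapGenerator(lambda d: y.data - 0.3)
        G_FC = MapGenerator(lambda d: x.data - 0.3)
        assert L.sobel_loss(x, y, G_CF, G_FC).item() == pytest.approx(0.0, abs=1e-6)

    def test_horizontal_ramp_interior_response_is_eight(self):
        """The 3x3 horizontal Sobel kernel applied to a unit-slope ramp gives
        8 per interior pixel; the vertical kernel gives 0."""
        ramp = np.tile(np.arange(8, dtype=np.float32), (8, 1))[None, None]
        fh = L.sobel_filter(Tensor(ramp), L.SOBEL_H).data[0, 0]
        fv = L.sobel_filter(Tensor(ramp), L.SOBEL_V).data[0, 0]
        assert np.allclose(fh[:, 1:-1], 8.0)
        assert np.allclose(fh[:, 0], 4.0) and np.allclose(fh[:, -1], 4.0)
        assert np.allclose(fv, 0.0)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (5, (0.0, 0.0, 0.0, 0.0)),
        (15, (5.0, 5.0, 1.0, 0.0)),
        (25, (10.0, 10.0, 10.0, 1e-4)),
    ])
    def test_three_phases(self, epoch, expected):
        w = L.loss_weights_for_epoch(epoch)
        assert (w.lambda_cycle, w.lambda_identity,
                w.lambda_generated, w.lambda_sobel) == expected
        assert w.lambda_adv == 1.0

    def test_breakpoints_are_sharp(self):
        assert L.loss_weights_for_epoch(9).lambda_cycle == 0.0
        assert L.loss_weights_for_epoch(10).lambda_cycle == 5.0
        assert L.loss_weights_for_epoch(19).lambda_cycle == 5.0
        assert L.loss_weights_for_epoch(20).lambda_cycle == 10.0

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            L.loss_weights_for_epoch(-1)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(lambda_cycle=-1.0)


class TestTotalGeneratorLoss:
    def _nets(self, g_cf, g_fc, d_f, d_c):
        return {"G_CF": g_cf, "G_FC": g_fc, "D_F": d_f, "D_C": d_c}

    def test_global_fixed_point_scores_zero(self, rng):
        xd = rng.random((2, 1, 4, 4)).astype(np.float32)
        nets = self._nets(IDENTITY, IDENTITY, ConstantCritic(0.0),
                          ConstantCritic(0.0))
        w = L.loss_weights_for_epoch(25)
        total, breakdown = L.total_generator_loss(Tensor(xd), Tensor(xd), nets, w)
        assert total.item() == pytest.approx(0.0, abs=1e-3)
        for term, val in breakdown.items():
            assert val == pytest.approx(0.0, abs=1e-4), term

    def test_total_is_dot_product_of_breakdown_and_weights(self, rng, tiny_nets):
        x = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        w = L.loss_weights_for_epoch(25)
        total, breakdown = L.total_generator_loss(x, y, tiny_nets, w)
        expected = (w.lambda_adv * breakdown["adv"]
                    + w.lambda_cycle * breakdown["cycle"]
                    + w.lambda_generated * breakdown["generated"]
                    + w.lambda_identity * breakdown["identity"]
                    + w.lambda_sobel * breakdown["sobel"])
        assert total.item() == pytest.approx(expected, rel=1e-5)

    def test_homogeneity_in_the_residual(self, rng):
        """Scaling the translation residual by alpha scales L_generated and
        L_sobel by exactly alpha (and the cycle term likewise)."""
        x = Tensor(rng.random((2, 1, 8, 8)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 8, 8)).astype(np.float32))
        r = rng.normal(0, 1, (2, 1, 8, 8)).astype(np.float32)

        def terms(alpha):
            G_CF = MapGenerator(lambda d: y.data - alpha * r)
            G_FC = MapGenerator(lambda d: x.data - alpha * r)
            gen = L.generated_loss(x, y, G_CF, G_FC).item()
            sob = L.sobel_loss(x, y, G_CF, G_FC).item()
            return gen, sob

        g1, s1 = terms(1.0)
        g3, s3 = terms(3.0)
        assert g3 == pytest.approx(3.0 * g1, rel=1e-4)
        assert s3 == pytest.approx(3.0 * s1, rel=1e-4)

    def test_skip_zero_reports_inactive_terms_as_zero(self, rng, tiny_nets):
        x = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        w = L.loss_weights_for_epoch(5)  # warm-up: only the adversarial term
        total, breakdown = L.total_generator_loss(x, y, tiny_nets, w,
                                                  skip_zero=True)
        assert breakdown["cycle"] == 0.0 and breakdown["sobel"] == 0.0
        assert total.item() == pytest.approx(breakdown["adv"], rel=1e-5)
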