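"""Training loop: schedules, determinism, alternation, checkpoints, inference."""

import numpy as np
import pytest

from cycledeblur import autodiff as ad
from cycledeblur import losses as L
from cycledeblur import nn
from cycledeblur import training as T
from cycledeblur.autodiff import Tensor
from cycledeblur.networks import DiscriminatorConfig, GeneratorConfig


def tiny_config(**kw):
    defaults = dict(
        epochs=1, batch_size=2, seed=0, checkpoint_every=1,
        augment=False, aug_crop=None,
        constant_lr_epochs=1, schedule_breakpoints=(1, 2),
        generator=GeneratorConfig(base_channels=4, n_residual_blocks=1),
        discriminator=DiscriminatorConfig(channels=(8, 16, 32),
                                          strides=(2, 2, 2)))
    defaults.update(kw)
    return T.TrainConfig(**defaults)


def tiny_pairs(rng, n=4, size=16):
    return [(rng.random((size, size)), rng.random((size, size)))
            for _ in range(n)]


class TestLearningRateSchedule:
    def test_constant_then_cosine_to_zero(self):
        cfg = T.TrainConfig(epochs=200, constant_lr_epochs=20, lr=1e-4)
        assert T.learning_rate_for_epoch(0, cfg) == 1e-4
        assert T.learning_rate_for_epoch(10, cfg) == 1e-4
        assert T.learning_rate_for_epoch(20, cfg) == 1e-4
        mid = T.learning_rate_for_epoch(110, cfg)
        assert 0 < mid < 1e-4
        assert T.learning_rate_for_epoch(200, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decay_after_warm_phase(self):
        cfg = T.TrainConfig(epochs=100, constant_lr_epochs=20)
        lrs = [T.learning_rate_for_epoch(e, cfg) for e in range(20, 101)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestAdam:
    def test_matches_reference_update_formula(self, rng):
        p = nn.Parameter(rng.normal(0, 1, (3,)))
        opt = T.Adam([p], lr=0.1, betas=(0.5, 0.999))
        g = np.array([1.0, -2.0, 0.5], dtype=np.float32)
        before = p.data.copy()
        opt.step([Tensor(g)])
        m_hat = ((1 - 0.5) * g) / (1 - 0.5)
        v_hat = ((1 - 0.999) * g * g) / (1 - 0.999)
        expected = before - 0.1 * m_hat / (np.sqrt(v_hat) + 1e-8)
        assert np.allclose(p.data, expected, atol=1e-6)


class TestTrainLoop:
    def test_iteration_and_checkpoint_counting(self, rng, tmp_path):
        pairs = tiny_pairs(rng, n=4)
        nets, history = T.train(pairs, tiny_config(), out_dir=tmp_path)
        assert len(history) == 2  # 4 pairs / batch 2 -> 2 iterations
        assert len(list(tmp_path.glob("checkpoint_*.npz"))) == 1
        assert (tmp_path / "history.jsonl").exists()

    def test_two_runs_identical_loss_curves(self, rng):
        pairs = tiny_pairs(rng, n=4)
        _, h1 = T.train(pairs, tiny_config(epochs=2))
        _, h2 = T.train(pairs, tiny_config(epochs=2))
        assert [r["generator_total"] for r in h1] == \
               [r["generator_total"] for r in h2]
        assert [r["critic_loss"] for r in h1] == \
               [r["critic_loss"] for r in h2]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            T.train([], tiny_config())

    def test_misaligned_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            T.train([(rng.random((16, 16)), rng.random((8, 8)))], tiny_config())

    def test_history_records_weights_and_terms(self, rng):
        pairs = tiny_pairs(rng, n=2)
        _, history = T.train(pairs, tiny_config(batch_size=2))
        rec = history[0]
        assert set(rec["terms"]) == {"adv", "cycle", "generated",
                                     "identity", "sobel"}
        assert rec["weights"]["lambda_adv"] == 1.0


class TestAlternation:
    """Critic and generator updates leave the other player untouched."""

    def _setup(self, rng):
        from cycledeblur.networks import build_networks
        nets = build_networks(
            GeneratorConfig(base_channels=4, n_residual_blocks=1),
            DiscriminatorConfig(channels=(8, 16, 32), strides=(2, 2, 2)),
            seed=0)
        x = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        y = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        return nets, x, y

    @staticmethod
    def _hashes(net):
        return {k: v.tobytes() for k, v in net.state_dict().items()}

    def test_critic_step_leaves_generators_unchanged(self, rng):
        nets, x, y = self._setup(rng)
        g_before = [self._hashes(nets["G_CF"]), self._hashes(nets["G_FC"])]
        disc_params = nets["D_F"].parameters() + nets["D_C"].parameters()
        opt = T.Adam(disc_params, lr=1e-3)
        with ad.no_grad():
            fy = nets["G_CF"](x).detach()
        loss = L.wgan_gp_critic_loss(nets["D_F"], y, fy, seed=0)
        opt.step(ad.grad(loss, disc_params))
        assert [self._hashes(nets["G_CF"]), self._hashes(nets["G_FC"])] == g_before
        assert self._hashes(nets["D_F"]) != self._hashes(nets["D_F"].__class__(
            nets["D_F"].config, rng=np.random.default_rng(0)))

    def test_generator_step_leaves_critics_unchanged(self, rng):
        nets, x, y = self._setup(rng)
        d_before = [self._hashes(nets["D_F"]), self._hashes(nets["D_C"])]
        gen_params = nets["G_CF"].parameters() + nets["G_FC"].parameters()
        disc_params = nets["D_F"].parameters() + nets["D_C"].parameters()
        opt = T.Adam(gen_params, lr=1e-3)
        with nn.frozen(disc_params):
            total, _ = L.total_generator_loss(x, y, nets,
                                              L.loss_weights_for_epoch(25))
            opt.step(ad.grad(total, gen_params))
        assert [self._hashes(nets["D_F"]), self._hashes(nets["D_C"])] == d_before
        assert all(p.requires_grad for p in disc_params)  # flags restored


class TestCheckpoints:
    def test_roundtrip_restores_identical_networks(self, rng, tmp_path):
        pairs = tiny_pairs(rng, n=2)
        cfg = tiny_config(batch_size=2)
        nets, _ = T.train(pairs, cfg, out_dir=tmp_path)
        path = next(tmp_path.glob("checkpoint_*.npz"))
        restored, meta = T.load_checkpoint(path, expect_config=cfg)
        for key in nets:
            s1, s2 = nets[key].state_dict(), restored[key].state_dict()
            assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        assert meta["epoch"] == 1

    def test_config_hash_mismatch_rejected(self, rng, tmp_path):
        pairs = tiny_pairs(rng, n=2)
        cfg = tiny_config(batch_size=2)
        T.train(pairs, cfg, out_dir=tmp_path)
        path = next(tmp_path.glob("checkpoint_*.npz"))
        other = tiny_config(batch_size=2, lr=5e-4)
        with pytest.raises(ValueError, match="hash"):
            T.load_checkpoint(path, expect_config=other)


class TestInference:
    def test_shape_and_window_contracts(self, tiny_nets, rng):
        cbct = rng.uniform(-1000, 300, (30, 33))  # awkward, non-multiple-of-4
        out = T.infer(cbct, tiny_nets["G_CF"])
        assert out.shape == (30, 33)
        assert out.min() >= -950.0 and out.max() <= 500.0

    def test_batch_order_preserved(self, tiny_nets, rng):
        slices = [rng.uniform(-1000, 300, (16, 16)) for _ in range(3)]
        outs = T.infer_batch(slices, tiny_nets["G_CF"])
        singles = [T.infer(s, tiny_nets["G_CF"]) for s in slices]
        assert all(np.array_equal(a, b) for a, b in zip(outs, singles))

    def test_anatomy_crop_size_passes_through(self, tiny_nets, rng):
        cbct = rng.uniform(-1000, 300, (264, 336))
        assert T.infer(cbct, tiny_nets["G_CF"]).shape == (264, 336)


def test_unpaired_mode_disables_alignment_dependent_terms(rng):
    pairs = tiny_pairs(rng, n=2)
    cfg = tiny_config(batch_size=2, paired=False,
                      schedule_breakpoints=(0, 0))  # full-loss phase at once
    _, history = T.train(pairs, cfg)
    rec = history[0]
    assert rec["weights"]["lambda_generated"] == 0.0
    assert rec["weights"]["lambda_sobel"] == 0.0
    assert rec["weights"]["lambda_cycle"] == 10.0  # unpaired terms survive


def test_small_profile_scales_schedule_proportionally():
    cfg = T.TrainConfig.small(epochs=19)
    b1, b2 = cfg.schedule_breakpoints
    assert b1 == 1 and b2 == 2  # 5% and 10% of the run, as in the full profile
    assert cfg.batch_size == 4
    assert cfg.generator.base_channels == 16
    assert cfg.generator.n_residual_blocks == 3
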