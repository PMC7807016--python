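"""Alternating critic/generator optimisation, checkpoints, and inference.

The regimen: Adam (learning rate 1e-4, beta1 0.5), batches of aligned
normalized pairs with synchronized augmentation, one critic update per
generator update by default, and a learning rate held constant for the
first 20 epochs then cosine-annealed to zero at the final epoch.  The
generator-loss weights follow the three-phase epoch schedule in
:mod:`cycledeblur.losses`.

Everything is reproducible: one integer seed fans out (via
``SeedSequence``) to network initialisation, batch sampling, augmentation,
and the gradient-penalty mixtures.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import losses as L
from . import nn
from . import preprocess as pp
from .autodiff import Tensor
from .networks import (DiscriminatorConfig, GeneratorConfig, build_networks)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr: float = 1e-4
    betas: tuple = (0.5, 0.999)
    constant_lr_epochs: int = 20
    critic_steps: int = 1
    schedule_breakpoints: tuple = (10, 20)
    gp_lambda: float = L.GP_LAMBDA_DEFAULT
    identity_mode: str = "literal"
    paired: bool = True          # False: unpaired data; L1/Sobel terms off
    seed: int = 0
    checkpoint_every: int = 50          # epochs between checkpoints
    augment: bool = True
    aug_rotation_deg: float = 20.0
    aug_crop: tuple | None = (128, 128)  # None: no crop (use full slices)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def small(cls, epochs: int = 19, seed: int = 0) -> "TrainConfig":
        """Desk-scale CPU profile: small networks, 64x64 full-slice batches.

        The schedule breakpoints keep the same fractions of the run as the
        full profile's 10/20 out of 200 epochs (5% and 10%), and the
        learning rate is raised to 2e-3: the full profile's 1e-4 is sized
        for hundreds of thousands of iterations, while this profile has a
        few hundred, so the per-step size scales up with the shortened
        schedule (the cosine decay still anneals it to zero).
        """
        b1 = max(1, round(0.05 * epochs))
        b2 = max(b1 + 1, round(0.10 * epochs))
        return cls(epochs=epochs, batch_size=4, seed=seed, lr=2e-3,
                   constant_lr_epochs=max(2, round(0.10 * epochs)),
                   schedule_breakpoints=(b1, b2),
                   checkpoint_every=max(1, epochs),
                   aug_crop=None, aug_rotation_deg=0.0,
                   generator=GeneratorConfig.small(),
                   discriminator=DiscriminatorConfig.small())

    def content_hash(self) -> str:
        import hashlib
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def learning_rate_for_epoch(epoch: int, config: TrainConfig) -> float:
    """Constant for the warm phase, then cosine annealing to zero."""
    e0 = config.constant_lr_epochs
    if epoch < e0:
        return config.lr
    span = max(config.epochs - e0, 1)
    t = min(epoch - e0, span)
    return config.lr * 0.5 * (1.0 + math.cos(math.pi * t / span))


class Adam:
    """Adam with bias correction; operates in-place on Parameter data."""

    def __init__(self, params, lr: float, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def state_dict(self):
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.asarray(a).copy() for a in state["m"]]
        self.v = [np.asarray(a).copy() for a in state["v"]]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, nets: dict, config: TrainConfig, epoch: int,
                    optimizers: dict | None = None) -> None:
    """All four networks (+ optimizer state) in one npz archive."""
    arrays = {}
    for net_name, net in nets.items():
        for k, arr in net.state_dict().items():
            arrays[f"net/{net_name}/{k}"] = arr
    if optimizers:
        for opt_name, opt in optimizers.items():
            st = opt.state_dict()
            arrays[f"opt/{opt_name}/t"] = np.array(st["t"])
            for i, a in enumerate(st["m"]):
                arrays[f"opt/{opt_name}/m/{i}"] = a
            for i, a in enumerate(st["v"]):
                arrays[f"opt/{opt_name}/v/{i}"] = a
    arrays["meta/epoch"] = np.array(epoch)
    meta = {"config_hash": config.content_hash(), "config": asdict(config)}
    arrays["meta/json"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path, expect_config: TrainConfig | None = None):
    """Rebuild the four networks from an archive; returns (nets, meta)."""
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays.pop("meta/json")).decode())
    epoch = int(arrays.pop("meta/epoch"))
    if expect_config is not None and meta["config_hash"] != expect_config.content_hash():
        raise ValueError(
            f"checkpoint config hash {meta['config_hash']} does not match "
            f"requested config {expect_config.content_hash()}")
    cfg = meta["config"]
    gen_cfg = GeneratorConfig(**{**cfg["generator"],
                                 "inception_kernels": tuple(cfg["generator"]["inception_kernels"]),
                                 "inception_weights": tuple(cfg["generator"]["inception_weights"])})
    disc_cfg = DiscriminatorConfig(**{**cfg["discriminator"],
                                      "channels": tuple(cfg["discriminator"]["channels"]),
                                      "strides": tuple(cfg["discriminator"]["strides"])})
    nets = build_networks(gen_cfg, disc_cfg, seed=0)
    for net_name, net in nets.items():
        prefix = f"net/{net_name}/"
        state = {k[len(prefix):]: v for k, v in arrays.items()
                 if k.startswith(prefix)}
        net.load_state_dict(state)
    meta["epoch"] = epoch
    return nets, meta


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _as_batch(pairs, idx):
    x = np.stack([pairs[i][0] for i in idx])[:, None]   # CBCT
    y = np.stack([pairs[i][1] for i in idx])[:, None]   # FBCT
    return x.astype(np.float32), y.astype(np.float32)


def train(pairs, config: TrainConfig, out_dir=None, nets: dict | None = None):
    """Train on a list of aligned, normalized (cbct, fbct) slice pairs.

    ``pairs`` holds 2-D arrays in [0, 1] (CBCT-like first).  Returns
    ``(nets, history)``; per-iteration loss breakdowns are appended to
    ``history.jsonl`` and checkpoints written when ``out_dir`` is given.
    """
    if len(pairs) == 0:
        raise ValueError("empty dataset")
    for cb, fb in pairs:
        if cb.shape != fb.shape:
            raise ValueError("pairs must be aligned (equal shapes)")

    ss = np.random.SeedSequence(config.seed)
    s_init, s_sample, s_aug, s_gp = [int(s.generate_state(1)[0]) % (2 ** 31)
                                     for s in ss.spawn(4)]
    if nets is None:
        nets = build_networks(config.generator, config.discriminator, seed=s_init)
    sample_rng = np.random.default_rng(s_sample)
    gp_rng = np.random.default_rng(s_gp)

    gen_params = nets["G_CF"].parameters() + nets["G_FC"].parameters()
    disc_params = nets["D_F"].parameters() + nets["D_C"].parameters()
    opt_g = Adam(gen_params, config.lr, config.betas)
    opt_d = Adam(disc_params, config.lr, config.betas)

    n = len(pairs)
    iters_per_epoch = max(1, n // config.batch_size)
    history = []
    out_dir = Path(out_dir) if out_dir is not None else None
    hist_file = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        hist_file = (out_dir / "history.jsonl").open("w")

    policy = None
    if config.augment:
        crop = config.aug_crop
        policy_size = crop if crop is not None else pairs[0][0].shape
        policy = pp.AugmentationPolicy(crop_size=tuple(policy_size),
                                       rotation_deg=config.aug_rotation_deg)

    nonfinite_streak = 0
    global_it = 0
    try:
        for epoch in range(config.epochs):
            lr = learning_rate_for_epoch(epoch, config)
            opt_g.lr = lr
            opt_d.lr = lr
            weights = L.loss_weights_for_epoch(
                epoch, breakpoints=config.schedule_breakpoints,
                gp_lambda=config.gp_lambda)
            if not config.paired:
                # alignment-dependent terms are meaningless on unpaired data
                weights = dataclasses.replace(weights, lambda_generated=0.0,
                                              lambda_sobel=0.0)
            for _ in range(iters_per_epoch):
                idx = sample_rng.choice(n, size=min(config.batch_size, n),
                                        replace=False)
                if policy is not None:
                    xs, ys = [], []
                    for i in idx:
                        a, b = pp.augment_pair(pairs[i][0], pairs[i][1], policy,
                                               seed=(s_aug + 977 * global_it + int(i)) % (2 ** 31))
                        xs.append(a)
                        ys.append(b)
                    xb = np.stack(xs)[:, None].astype(np.float32)
                    yb = np.stack(ys)[:, None].astype(np.float32)
                else:
                    xb, yb = _as_batch(pairs, idx)
                x_t, y_t = Tensor(xb), Tensor(yb)

                try:
                    # ---- critic steps (generator frozen: only critic params updated)
                    critic_loss = 0.0
                    for _ in range(config.critic_steps):
                        with ad.no_grad():
                            fake_y = nets["G_CF"](x_t).detach()
                            fake_x = nets["G_FC"](y_t).detach()
                        loss_d = ad.add(
                            L.wgan_gp_critic_loss(nets["D_F"], y_t, fake_y,
                                                  weights.gp_lambda, rng=gp_rng),
                            L.wgan_gp_critic_loss(nets["D_C"], x_t, fake_x,
                                                  weights.gp_lambda, rng=gp_rng))
                        grads_d = ad.grad(loss_d, disc_params)
                        opt_d.step(grads_d)
                        critic_loss = float(loss_d.data)

                    # ---- generator step (critics participate but are not updated)
                    with nn.frozen(disc_params):
                        total, breakdown = L.total_generator_loss(
                            x_t, y_t, nets, weights,
                            identity_mode=config.identity_mode, skip_zero=True)
                        grads_g = ad.grad(total, gen_params)
                    opt_g.step(grads_g)
                    nonfinite_streak = 0
                except FloatingPointError as err:
                    nonfinite_streak += 1
                    if nonfinite_streak >= 10:
                        raise RuntimeError(
                            f"non-finite losses for {nonfinite_streak} consecutive "
                            f"iterations at epoch {epoch}: {err}") from err
                    continue

                rec = {"epoch": epoch, "iteration": global_it, "lr": lr,
                       "critic_loss": critic_loss,
                       "generator_total": float(total.data),
                       "terms": breakdown,
                       "weights": {k: getattr(weights, k) for k in
                                   ("lambda_adv", "lambda_cycle", "lambda_generated",
                                    "lambda_identity", "lambda_sobel", "gp_lambda")}}
                history.append(rec)
                if hist_file is not None:
                    hist_file.write(json.dumps(rec) + "\n")
                global_it += 1

            if out_dir is not None and (
                    (epoch + 1) % config.checkpoint_every == 0
                    or epoch == config.epochs - 1):
                save_checkpoint(out_dir / f"checkpoint_epoch{epoch + 1:04d}.npz",
                                nets, config, epoch + 1,
                                optimizers={"generator": opt_g, "critic": opt_d})
    finally:
        if hist_file is not None:
            hist_file.close()

    return nets, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _pad_to_multiple(arr: np.ndarray, multiple: int = 4):
    h, w = arr.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)), mode="edge")
    return arr, (h, w)


def infer(cbct_hu, generator) -> np.ndarray:
    """Translate one CBCT-like HU slice to FBCT-like HU.

    normalize -> pad to a multiple of 4 -> G_CF -> unpad -> denormalize;
    outputs lie in the HU window [-950, 500] by the output activation.
    """
    norm = pp.normalize_hu(np.asarray(cbct_hu, dtype=np.float64))
    padded, (h, w) = _pad_to_multiple(norm)
    with ad.no_grad():
        out = generator(Tensor(padded[None, None].astype(np.float32)))
    res = np.asarray(out.data[0, 0, :h, :w], dtype=np.float64)
    return pp.denormalize(np.clip(res, 0.0, 1.0))


def infer_batch(cbct_list, generator):
    return [infer(c, generator) for c in cbct_list]


def infer_from_checkpoint(cbct_hu, checkpoint_path,
                          expect_config: TrainConfig | None = None):
    nets, _ = load_checkpoint(checkpoint_path, expect_config=expect_config)
    return infer(cbct_hu, nets["G_CF"])
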