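"""Generator and critic architectures for cycle-consistent CBCT deblurring.

Two generators are trained jointly: ``G_CF`` maps cone-beam CT (CBCT) slices
toward fan-beam CT (FBCT) appearance and ``G_FC`` maps the other way.  Each
is a residual encoder-decoder in the Deblur-GAN lineage whose two
downsampling stages are multi-kernel *inception* blocks: four parallel
convolutions with kernel sizes 1/5/9/13, each branch scaled by its kernel
size divided by the weight sum so large receptive fields dominate without
inflating activation scale, concatenated along channels.

The critics ``D_F`` and ``D_C`` are patch discriminators: fully
convolutional stacks without any final dense layer, so one instance scores
arbitrarily sized inputs and its parameter count is size-independent.
Normalisation is per-instance everywhere (never batch statistics), keeping
the per-sample gradient penalty well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn


@dataclass(frozen=True)
class GeneratorConfig:
    base_channels: int = 64
    n_residual_blocks: int = 9
    inception_kernels: tuple = (1, 5, 9, 13)
    inception_weights: tuple = (1.0, 5.0, 9.0, 13.0)
    activation: str = "swish"
    normalization: str = "instance"
    double_conv_residual: bool = False
    global_residual: bool = True

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.inception_kernels):
            raise ValueError("inception kernel sizes must be odd")
        if any(w <= 0 for w in self.inception_weights):
            raise ValueError("inception branch weights must be positive")
        if self.n_residual_blocks < 1:
            raise ValueError("need at least one residual block")

    @classmethod
    def small(cls) -> "GeneratorConfig":
        """Desk-scale profile for CPU runs: 16 base channels, 3 residual blocks."""
        return cls(base_channels=16, n_residual_blocks=3)


@dataclass(frozen=True)
class DiscriminatorConfig:
    channels: tuple = (64, 128, 256, 512)
    strides: tuple = (2, 2, 2, 2)
    leaky_slope: float = 0.2
    kernel: int = 4

    def __post_init__(self):
        if len(self.channels) < 3:
            raise ValueError("discriminator needs at least 3 convolution stages")
        if len(self.strides) != len(self.channels):
            raise ValueError("one stride per channel stage required")

    @classmethod
    def small(cls) -> "DiscriminatorConfig":
        return cls(channels=(16, 32, 64), strides=(2, 2, 2))


def _activation(name: str) -> nn.Module:
    if name == "swish":
        return nn.Swish()
    if name == "leaky_relu":
        return nn.LeakyReLU()
    raise ValueError(f"unknown activation {name!r}")


class InceptionBlock(nn.Module):
    """Four parallel convolutions (kernels 1/5/9/13) with weighted concat.

    Each branch produces ``out_ch // 4`` channels; branch outputs are scaled
    by ``weight / sum(weights)`` before concatenation.  Spatial size is
    preserved, or halved when ``downsample`` is set (stride 2).
    """

    def __init__(self, in_ch: int, out_ch: int, config: GeneratorConfig,
                 downsample: bool = False, *, rng):
        kernels = config.inception_kernels
        if out_ch % len(kernels) != 0:
            raise ValueError(
                f"output channels ({out_ch}) not divisible by the "
                f"{len(kernels)} inception branches")
        stride = 2 if downsample else 1
        branch_ch = out_ch // len(kernels)
        wsum = float(sum(config.inception_weights))
        self.scales = [w / wsum for w in config.inception_weights]
        self.branches = [
            nn.Conv2d(in_ch, branch_ch, k, stride=stride, padding=k // 2, rng=rng)
            for k in kernels
        ]
        self.norm = nn.InstanceNorm2d(out_ch)
        self.act = _activation(config.activation)

    def forward(self, x):
        outs = [ad.mul(b(x), s) for b, s in zip(self.branches, self.scales)]
        y = ad.concat(outs, axis=1)
        return self.act(self.norm(y))


class ResidualBlock(nn.Module):
    """conv3x3 -> instance norm -> Swish, with an additive skip."""

    def __init__(self, ch: int, config: GeneratorConfig, *, rng):
        self.conv1 = nn.Conv2d(ch, ch, 3, padding=1, rng=rng)
        self.norm1 = nn.InstanceNorm2d(ch)
        self.act = _activation(config.activation)
        if config.double_conv_residual:
            self.conv2 = nn.Conv2d(ch, ch, 3, padding=1, rng=rng)
            self.norm2 = nn.InstanceNorm2d(ch)
        else:
            self.conv2 = None

    def forward(self, x):
        y = self.act(self.norm1(self.conv1(x)))
        if self.conv2 is not None:
            y = self.norm2(self.conv2(y))
        return ad.add(x, y)


class Generator(nn.Module):
    """Residual encoder-decoder translating one-channel slices in [0, 1].

    Pipeline: 7x7 stride-1 convolution, two stride-2 inception blocks
    (x4 total downsampling), N residual blocks, two x2 transposed-convolution
    upsampling blocks, 7x7 output convolution, sigmoid into [0, 1].  Input
    height and width must each be divisible by 4 so the decoder restores the
    exact input size.

    By default (``global_residual``) the convolutional stack learns a
    *correction* added to the input in logit space before the output
    sigmoid — the defining trick of the deblurring-GAN lineage: the
    untrained network is already close to the identity, and training
    spends its budget on the artefacts instead of re-synthesising anatomy.
    The output range contract ([0, 1]) is unchanged.
    """

    def __init__(self, config: GeneratorConfig | None = None, *, rng):
        self.config = config = config or GeneratorConfig()
        c = config.base_channels
        self.head = nn.Sequential(
            nn.Conv2d(1, c, 7, padding=3, rng=rng),
            nn.InstanceNorm2d(c),
            _activation(config.activation),
        )
        self.down1 = InceptionBlock(c, 2 * c, config, downsample=True, rng=rng)
        self.down2 = InceptionBlock(2 * c, 4 * c, config, downsample=True, rng=rng)
        self.blocks = [ResidualBlock(4 * c, config, rng=rng)
                       for _ in range(config.n_residual_blocks)]
        self.up1 = nn.Sequential(
            nn.ConvTranspose2d(4 * c, 2 * c, rng=rng),
            nn.InstanceNorm2d(2 * c),
            _activation(config.activation),
        )
        self.up2 = nn.Sequential(
            nn.ConvTranspose2d(2 * c, c, rng=rng),
            nn.InstanceNorm2d(c),
            _activation(config.activation),
        )
        self.tail = nn.Conv2d(c, 1, 7, padding=3, rng=rng)

    def forward(self, x):
        x = ad.as_tensor(x)
        _, _, h, w = x.shape
        for axis, n in (("height", h), ("width", w)):
            if n % 4 != 0:
                raise ValueError(f"generator input {axis} ({n}) must be divisible by 4")
        y = self.head(x)
        y = self.down2(self.down1(y))
        for blk in self.blocks:
            y = blk(y)
        y = self.up2(self.up1(y))
        t = self.tail(y)
        if self.config.global_residual:
            xc = ad.clip(x, 1e-4, 1.0 - 1e-4)
            t = ad.add(t, ad.log(ad.div(xc, ad.sub(1.0, xc))))
        return ad.sigmoid(t)


class Discriminator(nn.Module):
    """Patch critic: strided convolutions ending in a 1-channel score map.

    The first stage is unnormalised; later stages use instance norm.  There
    is no pooling or dense head, so outputs are unbounded per-patch scores
    and any input at least the receptive-field size is accepted.
    """

    def __init__(self, config: DiscriminatorConfig | None = None, *, rng):
        self.config = config = config or DiscriminatorConfig()
        k = config.kernel
        layers = []
        in_ch = 1
        for i, (ch, s) in enumerate(zip(config.channels, config.strides)):
            layers.append(nn.Conv2d(in_ch, ch, k, stride=s, padding=k // 2, rng=rng))
            if i > 0:
                layers.append(nn.InstanceNorm2d(ch))
            layers.append(nn.LeakyReLU(config.leaky_slope))
            in_ch = ch
        layers.append(nn.Conv2d(in_ch, 1, k, stride=1, padding=k // 2, rng=rng))
        self.net = nn.Sequential(*layers)
        # smallest input whose score map is non-empty
        self.min_input = int(np.prod([s for s in config.strides]))

    def forward(self, x):
        x = ad.as_tensor(x)
        _, _, h, w = x.shape
        if h < self.min_input or w < self.min_input:
            raise ValueError(
                f"discriminator input {h}x{w} below minimum {self.min_input}")
        return self.net(x)


def build_networks(gen_config: GeneratorConfig | None = None,
                   disc_config: DiscriminatorConfig | None = None,
                   seed: int = 0) -> dict:
    """Construct the two generators and two critics with seeded init.

    Returns a dict with keys ``G_CF`` (CBCT->FBCT), ``G_FC`` (FBCT->CBCT),
    ``D_F`` (critic on the FBCT domain), ``D_C`` (critic on the CBCT domain).
    """
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    return {
        "G_CF": Generator(gen_config, rng=rngs[0]),
        "G_FC": Generator(gen_config, rng=rngs[1]),
        "D_F": Discriminator(disc_config, rng=rngs[2]),
        "D_C": Discriminator(disc_config, rng=rngs[3]),
    }
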