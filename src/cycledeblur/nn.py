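"""Minimal neural-network layer library on top of :mod:`cycledeblur.autodiff`.

Layers follow the familiar Module convention: parameters are discovered by
attribute traversal, ``state_dict``/``load_state_dict`` move plain numpy
arrays.  Weight initialisation is normal(0, 0.02), driven by an explicit
``numpy.random.Generator`` so network construction is reproducible.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor

INIT_STD = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


@contextmanager
def frozen(params):
    """Temporarily exclude ``params`` from gradient tracking.

    Used while updating the other player of the adversarial game: frozen
    parameters still participate in the forward pass but no weight-gradient
    work is recorded for them.
    """
    params = list(params)
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f


class Module:
    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=DTYPE).copy()

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, *, rng):
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(rng.normal(0.0, INIT_STD, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Upsampling transposed convolution; kernel 4, stride 2, pad 1 doubles H and W."""

    def __init__(self, in_ch, out_ch, kernel=4, stride=2, padding=1, bias=True, *, rng):
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(rng.normal(0.0, INIT_STD, (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ad.conv_transpose2d(x, self.weight, self.bias,
                                   stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    Uses no batch statistics, so it is compatible with the per-sample
    gradient penalty of the Wasserstein critic.
    """

    def __init__(self, ch, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        if affine:
            self.gamma = Parameter(np.ones((1, ch, 1, 1)))
            self.beta = Parameter(np.zeros((1, ch, 1, 1)))
        else:
            self.gamma = None
            self.beta = None

    def forward(self, x):
        mu = ad.mean(x, axis=(2, 3), keepdims=True)
        xc = ad.sub(x, mu)
        var = ad.mean(ad.mul(xc, xc), axis=(2, 3), keepdims=True)
        # multiply by the (tiny) reciprocal root rather than dividing the
        # full-size map: cheaper forward and much cheaper vjps
        inv = ad.power(ad.add(var, self.eps), -0.5)
        if self.gamma is not None:
            return ad.add(ad.mul(xc, ad.mul(inv, self.gamma)), self.beta)
        return ad.mul(xc, inv)


class Swish(Module):
    def forward(self, x):
        return ad.swish(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
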