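"""Loss terms of the cycle-consistent Wasserstein objective.

Critics are trained with the gradient-penalty Wasserstein loss; generators
minimise a weighted sum of five terms — adversarial, cycle-consistency,
paired ("generated") L1, identity, and Sobel edge loss — whose weights
follow a three-phase epoch schedule: a pure-adversarial warm-up, a
cycle-consistency phase, then the full objective with a small Sobel weight.

Norm conventions (fixed here and used consistently everywhere): the cycle
and identity terms use the per-image RMS of the residual (the L2 norm
normalised by the pixel count, averaged over the batch); the generated
term uses the mean absolute residual; the Sobel term is the mean absolute
value of the residual filtered with the two orthogonal 3x3 Sobel kernels
under edge-replicate padding (so a constant residual scores exactly
zero).  The pixel normalisation keeps all five terms on commensurate
scales so one weight schedule balances them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

GP_LAMBDA_DEFAULT = 10.0

SOBEL_H = np.array([[-1.0, 0.0, 1.0],
                    [-2.0, 0.0, 2.0],
                    [-1.0, 0.0, 1.0]], dtype=np.float32)
SOBEL_V = SOBEL_H.T.copy()


@dataclass(frozen=True)
class LossWeights:
    """Generator-loss coefficients plus the critic's gradient-penalty weight."""

    lambda_adv: float = 1.0
    lambda_cycle: float = 0.0
    lambda_generated: float = 0.0
    lambda_identity: float = 0.0
    lambda_sobel: float = 0.0
    gp_lambda: float = GP_LAMBDA_DEFAULT

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


def loss_weights_for_epoch(epoch: int, breakpoints=(10, 20),
                           gp_lambda: float = GP_LAMBDA_DEFAULT) -> LossWeights:
    """Piecewise-constant weight schedule with an adversarial warm-up.

    Epochs below the first breakpoint train like a vanilla (Wasserstein)
    GAN: all auxiliary weights zero.  Between the breakpoints the cycle
    period uses (cycle, identity, generated, sobel) = (5, 5, 1, 0); from
    the second breakpoint on, (10, 10, 10, 1e-4).  The adversarial weight
    is always 1.
    """
    if epoch < 0:
        raise ValueError(f"epoch must be nonnegative, got {epoch}")
    b1, b2 = breakpoints
    if epoch < b1:
        cyc, idt, gen, sob = 0.0, 0.0, 0.0, 0.0
    elif epoch < b2:
        cyc, idt, gen, sob = 5.0, 5.0, 1.0, 0.0
    else:
        cyc, idt, gen, sob = 10.0, 10.0, 10.0, 1e-4
    return LossWeights(lambda_adv=1.0, lambda_cycle=cyc, lambda_generated=gen,
                       lambda_identity=idt, lambda_sobel=sob,
                       gp_lambda=gp_lambda)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _scores(critic, batch) -> Tensor:
    """Per-sample scalar critic score: mean of the patch score map."""
    return ad.mean(critic(batch), axis=(1, 2, 3))


def _l2_image_norm(residual) -> Tensor:
    """Mean over batch of the per-image RMS (L2 norm / sqrt(n_pixels)).

    The pixel normalisation keeps the quadratic terms' gradient scale
    commensurate with the mean-absolute terms, so one set of weights
    balances all five losses; an unnormalised image norm would pull the
    generators toward the identity map with a gradient that never decays.
    """
    sq = ad.mean(ad.mul(residual, residual), axis=tuple(range(1, residual.ndim)))
    return ad.mean(ad.sqrt(ad.add(sq, 1e-12)))


def _l1_mean(residual) -> Tensor:
    return ad.mean(ad.abs_(residual))


def _pad_edge1(x: Tensor) -> Tensor:
    """1-pixel edge-replicate padding built from slices and concat."""
    x = ad.concat([x[:, :, 0:1, :], x, x[:, :, -1:, :]], axis=2)
    return ad.concat([x[:, :, :, 0:1], x, x[:, :, :, -1:]], axis=3)


def sobel_filter(image: Tensor, kernel: np.ndarray) -> Tensor:
    """3x3 Sobel filtering with edge-replicate padding (same size out)."""
    w = Tensor(kernel.reshape(1, 1, 3, 3))
    return ad.conv2d(_pad_edge1(image), w, stride=1, padding=0)


# ---------------------------------------------------------------------------
# critic loss
# ---------------------------------------------------------------------------

def gradient_penalty(critic, mix: Tensor) -> Tensor:
    """E[(||grad_input D(mix)||_2 - 1)^2] with per-sample gradients."""
    total = ad.sum_(_scores(critic, mix))
    gmix, = ad.grad(total, [mix], create_graph=True)
    sq = ad.sum_(ad.mul(gmix, gmix), axis=(1, 2, 3))
    gn = ad.sqrt(ad.add(sq, 1e-12))
    return ad.mean(ad.power(ad.sub(gn, 1.0), 2.0))


def wgan_gp_critic_loss(critic, real_batch, fake_batch,
                        gp_lambda: float = GP_LAMBDA_DEFAULT,
                        seed: int | None = None, rng=None) -> Tensor:
    """E[D(fake)] - E[D(real)] + gp_lambda * gradient penalty.

    The penalty is evaluated at per-sample convex mixtures
    eps*real + (1-eps)*fake with eps ~ U[0, 1]; the fake batch is detached
    so only critic parameters receive gradients.
    """
    real = ad.as_tensor(real_batch)
    fake = ad.as_tensor(fake_batch).detach()
    if real.shape != fake.shape:
        raise ValueError(f"batch shapes differ: {real.shape} vs {fake.shape}")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.uniform(0.0, 1.0, (real.shape[0], 1, 1, 1)).astype(np.float32)
    mix = Tensor(eps * real.data + (1 - eps) * fake.data, requires_grad=True)
    wasserstein = ad.sub(ad.mean(_scores(critic, fake)),
                         ad.mean(_scores(critic, real)))
    loss = ad.add(wasserstein, ad.mul(gp_lambda, gradient_penalty(critic, mix)))
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite critic loss (wasserstein={float(wasserstein.data)!r})")
    return loss


# ---------------------------------------------------------------------------
# generator loss terms
# ---------------------------------------------------------------------------

def adversarial_generator_loss(D_F, D_C, x, y, G_CF, G_FC) -> Tensor:
    """-E[D_F(G_CF(x))] - E[D_C(G_FC(y))]."""
    return ad.neg(ad.add(ad.mean(_scores(D_F, G_CF(x))),
                         ad.mean(_scores(D_C, G_FC(y)))))


def cycle_loss(x, y, G_CF, G_FC) -> Tensor:
    """Forward and backward cycle consistency (per-image residual RMS)."""
    x, y = ad.as_tensor(x), ad.as_tensor(y)
    return ad.add(_l2_image_norm(ad.sub(x, G_FC(G_CF(x)))),
                  _l2_image_norm(ad.sub(y, G_CF(G_FC(y)))))


def generated_loss(x, y, G_CF, G_FC) -> Tensor:
    """Paired L1 supervision: E|y - G_CF(x)| + E|x - G_FC(y)|.

    Requires aligned pairs; disable (weight zero) for unpaired training.
    """
    x, y = ad.as_tensor(x), ad.as_tensor(y)
    if x.shape != y.shape:
        raise ValueError("generated_loss requires an aligned pair of equal shape")
    return ad.add(_l1_mean(ad.sub(y, G_CF(x))), _l1_mean(ad.sub(x, G_FC(y))))


def identity_loss(x, y, G_CF, G_FC, mode: str = "literal") -> Tensor:
    """Re-application consistency of each generator (default), or the
    classic cross-domain identity variant.

    literal: E||G_CF(x) - G_CF(G_CF(x))|| + E||G_FC(y) - G_FC(G_FC(y))||
    classic: E||G_CF(y) - y|| + E||G_FC(x) - x||
    """
    x, y = ad.as_tensor(x), ad.as_tensor(y)
    if mode == "literal":
        yh = G_CF(x)
        xh = G_FC(y)
        return ad.add(_l2_image_norm(ad.sub(yh, G_CF(yh))),
                      _l2_image_norm(ad.sub(xh, G_FC(xh))))
    if mode == "classic":
        return ad.add(_l2_image_norm(ad.sub(G_CF(y), y)),
                      _l2_image_norm(ad.sub(G_FC(x), x)))
    raise ValueError(f"unknown identity mode {mode!r}")


def sobel_loss(x, y, G_CF, G_FC) -> Tensor:
    """Mean |Sobel(residual)| for both gradient directions and both
    translation directions (four terms summed); preserves edges that a
    plain L1 would smear."""
    x, y = ad.as_tensor(x), ad.as_tensor(y)
    ry = ad.sub(y, G_CF(x))
    rx = ad.sub(x, G_FC(y))
    total = None
    for r in (ry, rx):
        for k in (SOBEL_H, SOBEL_V):
            term = _l1_mean(sobel_filter(r, k))
            total = term if total is None else ad.add(total, term)
    return total


_TERM_FNS = {
    "adv": adversarial_generator_loss,
    "cycle": cycle_loss,
    "generated": generated_loss,
    "identity": identity_loss,
    "sobel": sobel_loss,
}


def total_generator_loss(x, y, nets: dict, weights: LossWeights,
                         identity_mode: str = "literal",
                         skip_zero: bool = False):
    """Weighted sum of the five generator terms.

    Returns ``(total, breakdown)`` where breakdown maps term name to its
    unweighted float value (for logging).  With ``skip_zero`` the terms
    whose weight is zero are not evaluated (reported as 0.0); intermediate
    generator outputs are shared across terms either way.
    """
    x, y = ad.as_tensor(x), ad.as_tensor(y)
    G_CF, G_FC = nets["G_CF"], nets["G_FC"]
    D_F, D_C = nets["D_F"], nets["D_C"]

    lam = {
        "adv": weights.lambda_adv,
        "cycle": weights.lambda_cycle,
        "generated": weights.lambda_generated,
        "identity": weights.lambda_identity,
        "sobel": weights.lambda_sobel,
    }
    active = {k for k, v in lam.items() if v > 0 or not skip_zero}

    yh = G_CF(x)   # synthetic FBCT
    xh = G_FC(y)   # synthetic CBCT
    terms: dict[str, Tensor] = {}
    if "adv" in active:
        terms["adv"] = ad.neg(ad.add(ad.mean(_scores(D_F, yh)),
                                     ad.mean(_scores(D_C, xh))))
    if "cycle" in active:
        terms["cycle"] = ad.add(_l2_image_norm(ad.sub(x, G_FC(yh))),
                                _l2_image_norm(ad.sub(y, G_CF(xh))))
    if "generated" in active:
        terms["generated"] = ad.add(_l1_mean(ad.sub(y, yh)),
                                    _l1_mean(ad.sub(x, xh)))
    if "identity" in active:
        if identity_mode == "literal":
            terms["identity"] = ad.add(_l2_image_norm(ad.sub(yh, G_CF(yh))),
                                       _l2_image_norm(ad.sub(xh, G_FC(xh))))
        else:
            terms["identity"] = identity_loss(x, y, G_CF, G_FC, mode=identity_mode)
    if "sobel" in active:
        total_s = None
        for r in (ad.sub(y, yh), ad.sub(x, xh)):
            for k in (SOBEL_H, SOBEL_V):
                t = _l1_mean(sobel_filter(r, k))
                total_s = t if total_s is None else ad.add(total_s, t)
        terms["sobel"] = total_s

    total = None
    breakdown = {}
    for name in ("adv", "cycle", "generated", "identity", "sobel"):
        if name in terms:
            val = float(terms[name].data)
            if not np.isfinite(val):
                raise FloatingPointError(f"non-finite generator loss term {name!r}")
            breakdown[name] = val
            contrib = ad.mul(lam[name], terms[name])
            total = contrib if total is None else ad.add(total, contrib)
        else:
            breakdown[name] = 0.0
    return total, breakdown
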