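"""Patch gather/scatter kernels behind the convolution primitives.

Zero-padding is folded into the gather bounds, so no padded copy of the
input is ever materialised.  JIT-compiled with numba when available (tight
copy loops beat numpy's strided slicing on the large multi-kernel
gathers); a pure-numpy fallback keeps the package importable without it.
Both paths produce identical results.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(**kwargs):
        def deco(fn):
            return fn
        return deco


@njit(cache=True)
def _im2col_loop(x, kh, kw, sh, sw, pad, out):
    B, C, H, W = x.shape
    oh, ow = out.shape[4], out.shape[5]
    for b in range(B):
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    # valid output columns: 0 <= j + z*sw - pad < W
                    z0 = max(0, -(-(pad - j) // sw))
                    z1 = min(ow, -(-(W + pad - j) // sw))
                    for y in range(oh):
                        yy = i + y * sh - pad
                        dst = out[b, c, i, j, y]
                        if yy < 0 or yy >= H:
                            dst[:] = 0.0
                            continue
                        src = x[b, c, yy]
                        for z in range(z0):
                            dst[z] = 0.0
                        for z in range(z0, z1):
                            dst[z] = src[j + z * sw - pad]
                        for z in range(z1, ow):
                            dst[z] = 0.0


@njit(cache=True)
def _col2im_loop(cols, sh, sw, pad, out):
    B, C, H, W = out.shape
    kh, kw, oh, ow = cols.shape[2], cols.shape[3], cols.shape[4], cols.shape[5]
    for b in range(B):
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    z0 = max(0, -(-(pad - j) // sw))
                    z1 = min(ow, -(-(W + pad - j) // sw))
                    for y in range(oh):
                        yy = i + y * sh - pad
                        if yy < 0 or yy >= H:
                            continue
                        src = cols[b, c, i, j, y]
                        dst = out[b, c, yy]
                        for z in range(z0, z1):
                            dst[j + z * sw - pad] += src[z]


def im2col_fill(x, kh, kw, sh, sw, pad, out6) -> None:
    """Fill ``out6`` (B, C, kh, kw, oh, ow) with patches of zero-padded ``x``."""
    if HAVE_NUMBA:
        _im2col_loop(x, kh, kw, sh, sw, pad, out6)
        return
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = out6.shape[4], out6.shape[5]
    for i in range(kh):
        for j in range(kw):
            out6[:, :, i, j] = x[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw]


def col2im_add(cols6, sh, sw, pad, out) -> None:
    """Scatter-add patches into ``out`` (adjoint of :func:`im2col_fill`)."""
    if HAVE_NUMBA:
        _col2im_loop(cols6, sh, sw, pad, out)
        return
    B, C, H, W = out.shape
    kh, kw, oh, ow = cols6.shape[2:]
    buf = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=out.dtype)
    for i in range(kh):
        for j in range(kw):
            buf[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += cols6[:, :, i, j]
    out += buf[:, :, pad:pad + H, pad:pad + W]
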