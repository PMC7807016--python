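"""Image-quality metrics and ROI CT-value statistics.

Conventions, fixed and enforced: MAE is computed on the normalized [0, 1]
intensity scale; MSE, PSNR and SSIM are computed after rescaling to the
16-bit integer range [0, 65535], with PSNR's MAX fixed at 65535.  SSIM
uses *global* region statistics (means, sample variances with the MN-1
denominator, and sample covariance over the whole region — no sliding
window), with stabilisers C1 = (0.01*L)^2 and C2 = (0.03*L)^2, L = 65535.
Region arguments are boolean masks; statistics use exactly the masked
pixels, never a bounding box.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MAX_I = 65535.0
C1 = (0.01 * MAX_I) ** 2
C2 = (0.03 * MAX_I) ** 2

METRIC_NAMES = ("mae", "mse", "psnr", "ssim")


def _region_values(ref, test, region):
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if region is None:
        return ref.ravel(), test.ravel()
    region = np.asarray(region, bool)
    if region.shape != ref.shape:
        raise ValueError(f"region shape {region.shape} != image shape {ref.shape}")
    if not region.any():
        raise ValueError("empty region")
    return ref[region], test[region]


def mae(ref, test, region=None) -> float:
    """Mean absolute error on the normalized [0, 1] scale."""
    r, t = _region_values(ref, test, region)
    return float(np.mean(np.abs(r - t)))


def mse(ref, test, region=None) -> float:
    """Mean squared error on the 16-bit scale (inputs in [0, 1] x 65535)."""
    r, t = _region_values(ref, test, region)
    d = (r - t) * MAX_I
    return float(np.mean(d * d))


def psnr(ref, test, region=None) -> float:
    """10*log10(65535^2 / MSE) in dB; +inf when the images agree exactly."""
    m = mse(ref, test, region)
    if m == 0.0:
        return math.inf
    return float(10.0 * np.log10(MAX_I ** 2 / m))


def ssim(ref, test, region=None) -> float:
    """Structural similarity from global region statistics.

    Sample statistics use the MN-1 denominator; the region must therefore
    contain at least two pixels.
    """
    r, t = _region_values(ref, test, region)
    if r.size < 2:
        raise ValueError("ssim needs a region of at least 2 pixels")
    x = r * MAX_I
    y = t * MAX_I
    mu_x = x.mean()
    mu_y = y.mean()
    var_x = np.sum((x - mu_x) ** 2) / (x.size - 1)
    var_y = np.sum((y - mu_y) ** 2) / (y.size - 1)
    cov = np.sum((x - mu_x) * (y - mu_y)) / (x.size - 1)
    num = (2 * mu_x * mu_y + C1) * (2 * cov + C2)
    den = (mu_x ** 2 + mu_y ** 2 + C1) * (var_x + var_y + C2)
    return float(num / den)


_METRICS = {"mae": mae, "mse": mse, "psnr": psnr, "ssim": ssim}


def roi_ct_stats(image_hu, rois: dict) -> dict:
    """Per-ROI (mean, sample SD) of CT values in HU, as 'mean +- SD' tables report."""
    img = np.asarray(image_hu, dtype=np.float64)
    out = {}
    for name, mask in rois.items():
        m = np.asarray(mask, bool)
        if not m.any():
            raise ValueError(f"empty ROI mask: {name!r}")
        vals = img[m]
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(vals.mean()), sd)
    return out


@dataclass
class MetricReport:
    """Per-method, per-ROI metric table plus ROI CT-value statistics."""

    rows: list = field(default_factory=list)       # dicts: method, roi, metric, value
    ct_stats: dict = field(default_factory=dict)   # method -> roi -> (mean, sd)
    pixel_counts: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows, columns=["method", "roi", "metric", "value"])

    def value(self, method: str, roi: str, metric: str) -> float:
        for row in self.rows:
            if (row["method"], row["roi"], row["metric"]) == (method, roi, metric):
                return row["value"]
        raise KeyError((method, roi, metric))

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out_dir / "report.csv", index=False)
        payload = {
            "rows": [
                {**r, "value": ("inf" if math.isinf(r["value"]) else r["value"])}
                for r in self.rows
            ],
            "ct_stats": self.ct_stats,
            "pixel_counts": self.pixel_counts,
        }
        (out_dir / "report.json").write_text(json.dumps(payload, indent=1))


def evaluate(pairs, rois_per_pair, methods: dict) -> MetricReport:
    """Score candidate translations against the FBCT reference per ROI.

    ``pairs``: list of (cbct_hu, fbct_hu) aligned slices.
    ``rois_per_pair``: one ROI-mask dict per pair.
    ``methods``: name -> list of candidate HU images (e.g. the raw CBCT
    input, or generator outputs), aligned with ``pairs``.

    Metrics are computed on normalized intensities pooled over all pairs'
    ROI pixels; CT statistics are reported in HU.
    """
    from . import preprocess as pp

    n = len(pairs)
    for name, imgs in methods.items():
        if len(imgs) != n:
            raise ValueError(f"method {name!r} supplies {len(imgs)} images "
                             f"for {n} pairs")
    if len(rois_per_pair) != n:
        raise ValueError("one ROI set per pair required")
    for (cb, fb), rois in zip(pairs, rois_per_pair):
        if cb.shape != fb.shape:
            raise ValueError("misaligned pair shapes")
        for rname, m in rois.items():
            if np.asarray(m).shape != fb.shape:
                raise ValueError(f"ROI {rname!r} shape mismatch")
    for name, imgs in methods.items():
        for im, (cb, _) in zip(imgs, pairs):
            if np.asarray(im).shape != cb.shape:
                raise ValueError(f"method {name!r} image shape mismatch")

    roi_names = list(rois_per_pair[0].keys())
    report = MetricReport()
    ref_norm = [pp.normalize_hu(fb) for _, fb in pairs]

    for method, imgs in methods.items():
        test_norm = [pp.normalize_hu(im) for im in imgs]
        report.ct_stats[method] = {}
        for roi in roi_names:
            ref_vals = np.concatenate([rn[np.asarray(rois[roi], bool)]
                                       for rn, rois in zip(ref_norm, rois_per_pair)])
            test_vals = np.concatenate([tn[np.asarray(rois[roi], bool)]
                                        for tn, rois in zip(test_norm, rois_per_pair)])
            for metric in METRIC_NAMES:
                val = _METRICS[metric](ref_vals, test_vals, None)
                report.rows.append({"method": method, "roi": roi,
                                    "metric": metric, "value": val})
            hu_vals = np.concatenate([np.asarray(im, dtype=np.float64)[np.asarray(rois[roi], bool)]
                                      for im, rois in zip(imgs, rois_per_pair)])
            sd = float(hu_vals.std(ddof=1)) if hu_vals.size > 1 else 0.0
            report.ct_stats[method][roi] = (float(hu_vals.mean()), sd)
            report.pixel_counts[roi] = int(hu_vals.size)
    return report
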