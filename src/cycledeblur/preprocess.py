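"""Image conditioning: body masking, HU windowing, cropping, augmentation.

The model operates on unit-interval intensities obtained by windowing
Hounsfield units to [-950, 500] (lung air up to trabecular bone) and
scaling linearly to [0, 1].  Values below/above the window clip to 0/1.
Body masking thresholds at CT value > -1000, keeps the largest connected
component, and fills its convex hull — which also removes the couch/air
gap ring that CBCT reconstructions carry outside the patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

WINDOW_LOW = -950.0
WINDOW_HIGH = 500.0
FILL_HU = -1000.0

#: crop target reproducing the 512x512 -> 264x336 anatomy crop
CROP_TARGET = (264, 336)


def normalize_hu(image, low: float = WINDOW_LOW, high: float = WINDOW_HIGH):
    """HU -> [0, 1]: out = clip((HU - low) / (high - low), 0, 1)."""
    img = np.asarray(image, dtype=np.float64)
    return np.clip((img - low) / (high - low), 0.0, 1.0)


def denormalize(image, low: float = WINDOW_LOW, high: float = WINDOW_HIGH):
    """[0, 1] -> HU; inverse of :func:`normalize_hu` on the window."""
    img = np.asarray(image, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("denormalize expects values in [0, 1]")
    return low + (high - low) * img


def body_mask(image, threshold: float = -1000.0):
    """Filled convex hull of the largest connected component above threshold."""
    img = np.asarray(image)
    fg = img > threshold
    if not fg.any():
        raise ValueError("empty body: no pixel above threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    return convex_hull_image(fg)


def apply_body_mask(image, mask, fill_hu: float = FILL_HU):
    """Set non-body pixels to air-like HU."""
    out = np.asarray(image, dtype=np.float64).copy()
    out[~np.asarray(mask, bool)] = fill_hu
    return out


def crop_to_anatomy(image, mask, target=CROP_TARGET, fill_hu: float = FILL_HU):
    """Crop a target-size window centred on the mask centroid.

    The window is shifted (clamped) to stay inside the source; if the source
    is smaller than the target along an axis the result is padded with
    air-equivalent HU.
    """
    img = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask: cannot locate anatomy")
    th, tw = target
    cy, cx = ndimage.center_of_mass(mask)
    out = np.full((th, tw), fill_hu, dtype=np.float64)
    y0 = int(round(cy - th / 2))
    x0 = int(round(cx - tw / 2))
    y0 = min(max(y0, 0), max(img.shape[0] - th, 0))
    x0 = min(max(x0, 0), max(img.shape[1] - tw, 0))
    ys = slice(y0, min(y0 + th, img.shape[0]))
    xs = slice(x0, min(x0 + tw, img.shape[1]))
    out[:ys.stop - ys.start, :xs.stop - xs.start] = img[ys, xs]
    return out


@dataclass(frozen=True)
class AugmentationPolicy:
    """Synchronized random crop / rotation / flips for aligned pairs."""

    crop_size: tuple = (128, 128)
    rotation_deg: float = 20.0          # angle drawn uniformly in +-rotation_deg
    flip_horizontal_p: float = 0.5
    flip_vertical_p: float = 0.5
    fill_value: float = 0.0             # background in normalized units

    def validate(self, image_shape) -> None:
        if self.rotation_deg < 0:
            raise ValueError("rotation range must be nonnegative")
        if (self.crop_size[0] > image_shape[0]
                or self.crop_size[1] > image_shape[1]):
            raise ValueError(
                f"crop {self.crop_size} larger than image {image_shape}")


def draw_augmentation(policy: AugmentationPolicy, image_shape, seed: int):
    """Draw one set of transform parameters (crop offset, angle, flips)."""
    policy.validate(image_shape)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ch, cw = policy.crop_size
    y0 = int(rng.integers(0, image_shape[0] - ch + 1))
    x0 = int(rng.integers(0, image_shape[1] - cw + 1))
    angle = float(rng.uniform(-policy.rotation_deg, policy.rotation_deg))
    flip_h = bool(rng.random() < policy.flip_horizontal_p)
    flip_v = bool(rng.random() < policy.flip_vertical_p)
    return y0, x0, angle, flip_h, flip_v


def augment_pair(first, second, policy: AugmentationPolicy, seed: int):
    """Apply one random crop, rotation, and flips identically to both images.

    The transform parameters are drawn once per call, so any pixelwise
    relation between the two inputs is preserved (up to interpolation) —
    the alignment contract paired training relies on.  Crop first, then
    rotate (bilinear, constant fill), then flips.
    """
    a = np.asarray(first, dtype=np.float64)
    b = np.asarray(second, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"pair shapes differ: {a.shape} vs {b.shape}")
    y0, x0, angle, flip_h, flip_v = draw_augmentation(policy, a.shape, seed)
    ch, cw = policy.crop_size

    def apply(img):
        out = img[y0:y0 + ch, x0:x0 + cw]
        if angle != 0.0:
            out = ndimage.rotate(out, angle, reshape=False, order=1,
                                 mode="constant", cval=policy.fill_value)
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        return np.ascontiguousarray(out)

    return apply(a), apply(b)


def read_dicom_hu(path):
    """Read a DICOM slice and apply RescaleSlope/RescaleIntercept to get HU."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept
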