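"""Synthetic chest-phantom simulator producing aligned FBCT/CBCT slice pairs.

Real cone-beam CT of the chest differs from planning fan-beam CT by spatial
blur, noise, smooth low-frequency shading from scatter, and large
tissue-dependent CT-value bias (e.g. breast tissue reading about -336 HU on
CBCT against -80 HU on FBCT).  This module renders parametric ellipse
phantoms of a thorax slice — body, muscle band, two lungs, mediastinum,
breast, sternum, spine — at reference (FBCT-like) CT values, then degrades
a copy with exactly those artefact classes to obtain the CBCT-like partner.
Every pair is aligned by construction and accompanied by one binary mask
per structure, so ROI statistics downstream are self-grounding.

All randomness flows from explicit integer seeds; per-pair seeds are
derived from the master seed and the pair index through
``numpy.random.SeedSequence``, so datasets are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

BACKGROUND_HU = -1000.0
HU_MIN, HU_MAX = -1024.0, 1500.0

#: reference (FBCT-like) mean CT value and within-structure texture SD, HU
REFERENCE_TISSUE_HU = {
    "body": (-60.0, 15.0),        # subcutaneous fat ring
    "muscle": (66.0, 9.0),
    "right_lung": (-775.0, 123.0),
    "left_lung": (-806.0, 34.0),
    "mediastinum": (48.0, 6.0),
    "breast": (-80.0, 20.0),
    "sternum": (245.0, 15.0),
    "spine": (304.0, 19.0),
}

#: CBCT-minus-FBCT mean CT-value offset per tissue, HU
CBCT_BIAS_HU = {
    "right_lung": -87.0,    # -862 - (-775)
    "left_lung": -87.0,     # -893 - (-806)
    "breast": -256.0,       # -336 - (-80)
    "mediastinum": -185.0,  # -137 - 48
    "muscle": -178.0,       # -112 - 66
    "sternum": -79.0,       # 166 - 245
    "spine": -221.0,        # 83 - 304
}

#: painting order, back to front; later structures overwrite earlier ones
PAINT_ORDER = ("body", "muscle", "right_lung", "left_lung",
               "mediastinum", "breast", "sternum", "spine")

#: the seven evaluation ROIs (everything except the body/fat ring)
ROI_NAMES = ("right_lung", "left_lung", "breast", "mediastinum",
             "muscle", "sternum", "spine")


@dataclass(frozen=True)
class Ellipse:
    """Axis lengths and center in pixels, rotation in degrees."""
    cy: float
    cx: float
    ay: float
    ax: float
    rot_deg: float = 0.0

    def footprint(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        dy = yy - self.cy
        dx = xx - self.cx
        th = np.deg2rad(self.rot_deg)
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        return (u / self.ay) ** 2 + (v / self.ax) ** 2 <= 1.0


# relative geometry (fractions of height/width) of the default thorax slice
_DEFAULT_GEOMETRY = {
    "body": (0.52, 0.50, 0.40, 0.46, 0.0),
    "muscle": (0.52, 0.50, 0.355, 0.415, 0.0),
    "right_lung": (0.48, 0.29, 0.175, 0.115, 8.0),
    "left_lung": (0.48, 0.71, 0.175, 0.115, -8.0),
    "mediastinum": (0.50, 0.50, 0.14, 0.085, 0.0),
    "breast": (0.24, 0.60, 0.07, 0.115, -10.0),
    "sternum": (0.20, 0.50, 0.028, 0.055, 0.0),
    "spine": (0.80, 0.50, 0.055, 0.048, 0.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue CT values of one synthetic thorax slice."""

    height: int = 128
    width: int = 128
    ellipses: dict = field(default_factory=dict)      # name -> Ellipse
    mean_hu: dict = field(default_factory=dict)       # name -> HU
    texture_sd: dict = field(default_factory=dict)    # name -> HU
    background_hu: float = BACKGROUND_HU

    @classmethod
    def default(cls, height: int = 128, width: int = 128) -> "PhantomSpec":
        ellipses = {
            name: Ellipse(cy * height, cx * width, ay * height, ax * width, rot)
            for name, (cy, cx, ay, ax, rot) in _DEFAULT_GEOMETRY.items()
        }
        return cls(
            height=height, width=width, ellipses=ellipses,
            mean_hu={k: v[0] for k, v in REFERENCE_TISSUE_HU.items()},
            texture_sd={k: v[1] for k, v in REFERENCE_TISSUE_HU.items()},
        )

    def validate(self) -> None:
        if set(self.ellipses) != set(PAINT_ORDER):
            raise ValueError(
                f"spec must define exactly the structures {PAINT_ORDER}")
        for name, mu in self.mean_hu.items():
            if not (HU_MIN <= mu <= HU_MAX):
                raise ValueError(f"mean HU of {name!r} ({mu}) outside "
                                 f"[{HU_MIN}, {HU_MAX}]")
        for name, sd in self.texture_sd.items():
            if sd < 0:
                raise ValueError(f"texture SD of {name!r} must be nonnegative")
        feet = {n: e.footprint(self.height, self.width)
                for n, e in self.ellipses.items()}
        body = feet["body"]
        offenders = [n for n in PAINT_ORDER if n != "body"
                     and np.any(feet[n] & ~body)]
        if offenders:
            raise ValueError(f"structures outside the body ellipse: {offenders}")
        bone = feet["sternum"] | feet["spine"]
        clash = [n for n in ("right_lung", "left_lung")
                 if np.any(feet[n] & bone)]
        if clash:
            raise ValueError(f"lungs overlap bone structures: {clash}")

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "height": self.height, "width": self.width,
                "background_hu": self.background_hu,
                "ellipses": {k: vars(v) for k, v in sorted(self.ellipses.items())},
                "mean_hu": dict(sorted(self.mean_hu.items())),
                "texture_sd": dict(sorted(self.texture_sd.items())),
            },
            sort_keys=True, default=float,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DegradationParams:
    """Artefact model turning an FBCT-like slice into a CBCT-like one.

    Applied in a fixed order: per-tissue CT-value bias, smooth additive
    shading, isotropic Gaussian blur, white noise.  All-zero parameters give
    the identity degradation.
    """

    blur_sigma_px: float = 1.5
    noise_sd_hu: float = 20.0
    shading_amplitude_hu: float = 30.0
    shading_length_px: float = 64.0
    bias_hu: dict = field(default_factory=lambda: dict(CBCT_BIAS_HU))

    def validate(self, roi_names=None) -> None:
        for fname in ("blur_sigma_px", "noise_sd_hu",
                      "shading_amplitude_hu", "shading_length_px"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be nonnegative")
        if roi_names is not None:
            unknown = set(self.bias_hu) - set(roi_names)
            if unknown:
                raise ValueError(f"bias keys not among ROI masks: {sorted(unknown)}")

    @classmethod
    def identity(cls) -> "DegradationParams":
        return cls(blur_sigma_px=0.0, noise_sd_hu=0.0,
                   shading_amplitude_hu=0.0, bias_hu={})


def generate_phantom(spec: PhantomSpec, seed: int):
    """Render one FBCT-like HU image and its per-structure masks.

    Structures are painted back to front; each mask is the set of pixels
    whose top-most structure is that one, so masks partition the body.
    Deterministic for fixed (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    img = np.full((spec.height, spec.width), spec.background_hu, dtype=np.float64)
    owner = np.full((spec.height, spec.width), -1, dtype=np.int8)
    for i, name in enumerate(PAINT_ORDER):
        foot = spec.ellipses[name].footprint(spec.height, spec.width)
        n = int(foot.sum())
        tex = rng.normal(0.0, 1.0, n) * spec.texture_sd.get(name, 0.0)
        img[foot] = spec.mean_hu[name] + tex
        owner[foot] = i
    masks = {name: owner == i for i, name in enumerate(PAINT_ORDER)}
    return img, masks


def shading_field(shape, amplitude_hu, length_px, rng) -> np.ndarray:
    """Smooth low-frequency field: sum of three oriented cosine terms.

    Emulates the first-order effect of scatter — a spatially slowly varying
    CT-value error — without any projection-domain physics.
    """
    if amplitude_hu == 0:
        return np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    out = np.zeros(shape)
    for _ in range(3):
        theta = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 1.0) / max(length_px, 1e-9)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.cos(2 * np.pi * freq *
                      (yy * np.sin(theta) + xx * np.cos(theta)) + phase)
    return amplitude_hu * out / 3.0


def degrade_to_cbct(fbct: np.ndarray, rois: dict,
                    params: DegradationParams, seed: int) -> np.ndarray:
    """Apply the CBCT artefact model to an FBCT-like slice.

    Order of operations is part of the contract: tissue bias, shading,
    blur, noise.  Output geometry equals input geometry.
    """
    params.validate(roi_names=rois.keys())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.asarray(fbct, dtype=np.float64).copy()
    for name, offset in params.bias_hu.items():
        out[rois[name]] += offset
    out += shading_field(out.shape, params.shading_amplitude_hu,
                         params.shading_length_px, rng)
    if params.blur_sigma_px > 0:
        out = ndimage.gaussian_filter(out, params.blur_sigma_px)
    if params.noise_sd_hu > 0:
        out += rng.normal(0.0, params.noise_sd_hu, out.shape)
    return out


def jitter_spec(spec: PhantomSpec, rng,
                axis_frac: float = 0.05, center_px: float = 3.0) -> PhantomSpec:
    """Perturb structure positions/sizes for inter-pair anatomical variation."""
    new = {}
    for name, e in spec.ellipses.items():
        new[name] = Ellipse(
            cy=e.cy + rng.uniform(-center_px, center_px),
            cx=e.cx + rng.uniform(-center_px, center_px),
            ay=e.ay * (1 + rng.uniform(-axis_frac, axis_frac)),
            ax=e.ax * (1 + rng.uniform(-axis_frac, axis_frac)),
            rot_deg=e.rot_deg + rng.uniform(-2.0, 2.0),
        )
    return replace(spec, ellipses=new)


def _valid_jitter(spec: PhantomSpec, rng, max_tries: int = 20) -> PhantomSpec:
    # jitter can push a lung onto bone at small image sizes; redraw until valid
    for _ in range(max_tries):
        cand = jitter_spec(spec, rng)
        try:
            cand.validate()
            return cand
        except ValueError:
            continue
    return spec


def make_pair(spec: PhantomSpec, params: DegradationParams,
              master_seed: int, index: int, jitter: bool = True):
    """One aligned (fbct, cbct, masks) triple; seeded from (master, index)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    s_jit, s_render, s_degrade = [int(s.generate_state(1)[0]) % (2**31)
                                  for s in ss.spawn(3)]
    if jitter:
        spec = _valid_jitter(spec, np.random.default_rng(s_jit))
    fbct, masks = generate_phantom(spec, s_render)
    cbct = degrade_to_cbct(fbct, masks, params, s_degrade)
    return fbct, cbct, masks


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

HU_PNG_OFFSET = 1024  # stored value = HU + offset, clipped to uint16


def write_hu_png(path, img_hu: np.ndarray) -> None:
    import imageio.v3 as iio
    stored = np.clip(np.round(np.asarray(img_hu) + HU_PNG_OFFSET), 0, 65535)
    iio.imwrite(str(path), stored.astype(np.uint16))
    Path(str(path) + ".json").write_text(
        json.dumps({"hu_offset": HU_PNG_OFFSET, "dtype": "uint16"}))


def read_hu_png(path) -> np.ndarray:
    import imageio.v3 as iio
    sidecar = Path(str(path) + ".json")
    offset = HU_PNG_OFFSET
    if sidecar.exists():
        offset = json.loads(sidecar.read_text())["hu_offset"]
    return iio.imread(str(path)).astype(np.float64) - offset


def write_mask_png(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio
    iio.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask_png(path) -> np.ndarray:
    import imageio.v3 as iio
    return iio.imread(str(path)) > 127


def generate_dataset(n_pairs: int, out_dir, spec: PhantomSpec | None = None,
                     params: DegradationParams | None = None,
                     seed: int = 0, jitter: bool = True) -> dict:
    """Write ``n_pairs`` aligned FBCT/CBCT pairs plus masks and a manifest.

    Re-running with identical arguments reproduces identical files.
    Returns the manifest dict.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    spec = spec or PhantomSpec.default()
    params = params or DegradationParams()
    spec.validate()
    params.validate(roi_names=PAINT_ORDER)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_pairs):
        fbct, cbct, masks = make_pair(spec, params, seed, i, jitter=jitter)
        pdir = out_dir / f"pair_{i:04d}"
        pdir.mkdir(exist_ok=True)
        write_hu_png(pdir / "fbct.png", fbct)
        write_hu_png(pdir / "cbct.png", cbct)
        mask_files = {}
        for name in ROI_NAMES:
            write_mask_png(pdir / f"mask_{name}.png", masks[name])
            mask_files[name] = f"pair_{i:04d}/mask_{name}.png"
        entries.append({
            "index": i,
            "fbct": f"pair_{i:04d}/fbct.png",
            "cbct": f"pair_{i:04d}/cbct.png",
            "masks": mask_files,
            "seed": seed,
        })
    manifest = {
        "n_pairs": n_pairs,
        "master_seed": seed,
        "spec_hash": spec.content_hash(),
        "hu_offset": HU_PNG_OFFSET,
        "pairs": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(data_dir):
    """Read a generated dataset back as (fbct, cbct, masks) triples in HU."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    out = []
    for entry in manifest["pairs"]:
        fbct = read_hu_png(data_dir / entry["fbct"])
        cbct = read_hu_png(data_dir / entry["cbct"])
        masks = {name: read_mask_png(data_dir / rel)
                 for name, rel in entry["masks"].items()}
        out.append((fbct, cbct, masks))
    return out, manifest
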