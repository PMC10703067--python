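"""Ultrasound-like phantom generation and the offline augmentation pipeline.

Real ultrasound frames are characterised by multiplicative speckle noise, low
signal-to-noise ratio, blurred boundaries and targets of widely varying size
and shape — ring-like cross-sections (fetal head) and small irregular blobs
(nerve bundles), with some frames containing no target at all.  The phantom
generator emulates that statistical structure so the whole pipeline is
exercisable without external data: a foreground shape on a darker
background, Gaussian boundary blur, then multiplicative speckle, quantized
to 8 bits.  It makes no attempt at physical realism (no beamforming or
attenuation modelling).

Augmentation follows the offline x5 scheme: each sample yields itself plus
a horizontal flip, a vertical flip, one random rescale and one random
rotation, with nearest-neighbour interpolation on masks so they stay binary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomSpec", "Sample", "generate_phantom", "augment", "augment_dataset",
    "crop_resize", "build_dataset", "load_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom ensemble.

    ``size_range`` bounds the target's characteristic diameter as a fraction
    of the image diagonal; ``speckle_strength`` scales the multiplicative
    noise; ``empty_mask_prob`` is the fraction of frames with no target.
    """

    image_size: int = 320
    target_kind: str = "blob"          # "ring" or "blob"
    size_range: tuple = (0.1, 0.35)
    speckle_strength: float = 0.35
    boundary_blur_sigma: float = 1.5
    empty_mask_prob: float = 0.0
    seed: int = 0
    contrast: float = 0.45             # foreground minus background intensity
    speckle_model: str = "gaussian"    # or "rayleigh"

    def validate(self) -> None:
        if self.image_size <= 0:
            raise ValueError(f"image_size: {self.image_size} must be positive")
        if self.target_kind not in ("ring", "blob"):
            raise ValueError(f"target_kind: unknown kind {self.target_kind!r}")
        lo, hi = self.size_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"size_range: need 0 < min <= max, got {self.size_range}")
        if self.speckle_strength < 0:
            raise ValueError(f"speckle_strength: {self.speckle_strength} must be >= 0")
        if self.boundary_blur_sigma < 0:
            raise ValueError(
                f"boundary_blur_sigma: {self.boundary_blur_sigma} must be >= 0")
        if not 0.0 <= self.empty_mask_prob <= 1.0:
            raise ValueError(
                f"empty_mask_prob: {self.empty_mask_prob} not in [0, 1]")
        if self.speckle_model not in ("gaussian", "rayleigh"):
            raise ValueError(f"speckle_model: unknown model {self.speckle_model!r}")


@dataclass
class Sample:
    """One grayscale image with its binary mask.

    ``image`` holds intensities in [0, 1]; ``mask`` is {0, 1}; ``spacing`` is
    the physical pixel size in mm/px used by the surface-distance metrics.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing: float = 1.0
    id: str = ""

    def validate(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary {0,1}")


def _shape_mask(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Rasterize one star-convex target (annulus for rings, lumpy disc for blobs)."""
    n = spec.image_size
    diag = np.sqrt(2.0) * n
    lo, hi = spec.size_range
    diameter = rng.uniform(lo, hi) * diag
    r_out = diameter / 2.0
    margin = min(r_out, n / 2 - 1)
    cy = rng.uniform(margin, n - margin)
    cx = rng.uniform(margin, n - margin)
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # star-convex radial perturbation keeps the component connected
    wobble = np.zeros_like(theta)
    n_lobes = rng.integers(3, 7)
    for k in range(2, 2 + n_lobes):
        amp = rng.uniform(0.0, 0.18 / np.sqrt(k))
        phase = rng.uniform(0, 2 * np.pi)
        wobble += amp * np.cos(k * theta + phase)
    radius = r_out * (1.0 + wobble)
    if spec.target_kind == "ring":
        thickness = rng.uniform(0.18, 0.35)
        mask = (rr <= radius) & (rr >= radius * (1.0 - thickness))
    else:
        mask = rr <= radius
    return mask.astype(np.uint8)


def generate_phantom(spec: PhantomSpec, index: int) -> Sample:
    """Deterministically generate phantom ``index`` of the ensemble ``spec``.

    The random stream is derived from ``(spec.seed, index)``, so identical
    arguments yield bit-identical samples regardless of call order.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(index)]))
    n = spec.image_size
    if rng.uniform() < spec.empty_mask_prob:
        mask = np.zeros((n, n), dtype=np.uint8)
    else:
        mask = _shape_mask(rng, spec)
    bg, fg = 0.5 - spec.contrast / 2, 0.5 + spec.contrast / 2
    image = np.where(mask > 0, fg, bg)
    if spec.boundary_blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.boundary_blur_sigma,
                                        mode="nearest")
    if spec.speckle_strength > 0:
        if spec.speckle_model == "gaussian":
            noise = 1.0 + spec.speckle_strength * rng.standard_normal((n, n))
        else:
            ray = rng.rayleigh(scale=1.0, size=(n, n))
            ray /= np.sqrt(np.pi / 2)  # unit mean
            noise = 1.0 + spec.speckle_strength * (ray - 1.0)
        image = image * noise
    image = np.clip(image, 0.0, 1.0)
    image = np.round(image * 255.0) / 255.0  # 8-bit quantization (lossless PNG IO)
    return Sample(image=image, mask=mask, spacing=1.0, id=f"phantom_{index:05d}")


def _resample(img: np.ndarray, zoom: float, order: int, out_size: tuple,
              cval: float, mode: str) -> np.ndarray:
    """Zoom about the centre and crop/pad back to ``out_size``."""
    if mode == "constant":
        mode = "grid-constant"
    z = ndimage.zoom(img, zoom, order=order, mode=mode, cval=cval,
                     grid_mode=True, prefilter=order > 1)
    out = np.full(out_size, cval, dtype=img.dtype)
    h, w = z.shape
    oh, ow = out_size
    sy, sx = max(0, (h - oh) // 2), max(0, (w - ow) // 2)
    dy, dx = max(0, (oh - h) // 2), max(0, (ow - w) // 2)
    ch, cw = min(h, oh), min(w, ow)
    out[dy:dy + ch, dx:dx + cw] = z[sy:sy + ch, sx:sx + cw]
    return out


def augment(sample: Sample, scale_range: tuple = (0.8, 1.25),
            rotation_range: float = 15.0, seed: int = 0) -> list:
    """Offline x5 augmentation: [original, h-flip, v-flip, scale, rotation].

    Flips are exact (mask cardinality preserved); scaling keeps the canvas
    fixed (zoom about the centre, then crop or zero-pad); rotation uses
    reflection padding for the image and zero padding for the mask.  Masks
    are resampled with nearest-neighbour interpolation so they stay binary.
    """
    sample.validate()
    rng = np.random.default_rng(seed)
    img, msk = sample.image, sample.mask
    out = [replace(sample, id=sample.id + "_orig")]
    out.append(Sample(img[:, ::-1].copy(), msk[:, ::-1].copy(),
                      sample.spacing, sample.id + "_hflip"))
    out.append(Sample(img[::-1, :].copy(), msk[::-1, :].copy(),
                      sample.spacing, sample.id + "_vflip"))
    zoom = rng.uniform(*scale_range)
    size = img.shape
    s_img = _resample(img, zoom, 1, size, float(img.mean()), "nearest")
    s_msk = _resample(msk.astype(np.uint8), zoom, 0, size, 0, "constant")
    out.append(Sample(_quantize(s_img), s_msk, sample.spacing,
                      sample.id + "_scale"))
    angle = rng.uniform(-rotation_range, rotation_range)
    r_img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
    r_msk = ndimage.rotate(msk.astype(np.uint8), angle, reshape=False, order=0,
                           mode="constant", cval=0)
    out.append(Sample(_quantize(r_img), r_msk, sample.spacing,
                      sample.id + "_rot"))
    return out


def _quantize(img: np.ndarray) -> np.ndarray:
    """Clip to [0,1] and snap to the 8-bit grid so PNG round-trips are exact."""
    return np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0


def augment_dataset(samples, scale_range: tuple = (0.8, 1.25),
                    rotation_range: float = 15.0, seed: int = 0) -> list:
    """Apply :func:`augment` to every sample; the pool grows exactly x5."""
    pool = []
    for i, s in enumerate(samples):
        pool.extend(augment(s, scale_range, rotation_range,
                            seed=np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31)))
    return pool


def crop_resize(sample: Sample, size: int) -> Sample:
    """Centre-crop to square aspect, then resize to ``size`` x ``size``.

    The image is resampled bilinearly, the mask with nearest neighbour, and
    the pixel spacing is rescaled by the same factor so physical distances
    are preserved.
    """
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    sample.validate()
    img, msk = sample.image, sample.mask
    h, w = img.shape
    side = min(h, w)
    y0, x0 = (h - side) // 2, (w - side) // 2
    img = img[y0:y0 + side, x0:x0 + side]
    msk = msk[y0:y0 + side, x0:x0 + side]
    if side != size:
        zoom = size / side
        img = ndimage.zoom(img, zoom, order=1, mode="nearest", grid_mode=True)
        msk = ndimage.zoom(msk.astype(np.uint8), zoom, order=0, mode="nearest",
                           grid_mode=True)
        img = img[:size, :size]
        msk = msk[:size, :size]
        spacing = sample.spacing * side / size
    else:
        spacing = sample.spacing
    # guard against off-by-one from zoom rounding
    if img.shape != (size, size):
        img = _resample(img, 1.0, 1, (size, size), float(img.mean()), "nearest")
        msk = _resample(msk, 1.0, 0, (size, size), 0, "constant")
    return Sample(_quantize(img), msk.astype(np.uint8), spacing,
                  sample.id + f"_c{size}")


def write_sample(sample: Sample, image_path: str, mask_path: str) -> None:
    iio.imwrite(image_path, np.round(sample.image * 255).astype(np.uint8))
    iio.imwrite(mask_path, (sample.mask * 255).astype(np.uint8))


def read_sample(image_path: str, mask_path: str, spacing: float = 1.0,
                sample_id: str = "") -> Sample:
    image = np.asarray(iio.imread(image_path), dtype=np.float64) / 255.0
    mask = (np.asarray(iio.imread(mask_path)) > 127).astype(np.uint8)
    return Sample(image=image, mask=mask, spacing=spacing, id=sample_id)


def build_dataset(n: int, spec: PhantomSpec, augment_flag: bool,
                  out_dir: str) -> pd.DataFrame:
    """Generate ``n`` phantoms (x5 if augmenting), write PNG pairs + manifest.

    Returns the manifest DataFrame (id, image_path, mask_path, spacing_mm);
    the same table is written to ``out_dir/manifest.csv``.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    spec.validate()
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n):
        sample = generate_phantom(spec, i)
        variants = augment(sample, seed=spec.seed * 100003 + i) if augment_flag \
            else [sample]
        for v in variants:
            image_path = os.path.join(out_dir, f"{v.id}_img.png")
            mask_path = os.path.join(out_dir, f"{v.id}_mask.png")
            write_sample(v, image_path, mask_path)
            rows.append({"id": v.id, "image_path": image_path,
                         "mask_path": mask_path, "spacing_mm": v.spacing})
    manifest = pd.DataFrame(rows, columns=["id", "image_path", "mask_path",
                                           "spacing_mm"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def load_dataset(manifest: str | pd.DataFrame) -> list:
    """Read samples back from a manifest (path or DataFrame)."""
    if isinstance(manifest, str):
        manifest = pd.read_csv(manifest)
    return [read_sample(r.image_path, r.mask_path, float(r.spacing_mm), r.id)
            for r in manifest.itertuples()]
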