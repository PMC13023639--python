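"""Synthetic intravascular-OCT vessel phantoms and training augmentations.

A phantom frame emulates the qualitative structure of a catheter OCT
cross-section: a dark circular lumen (a small fraction of the image
area), a bright vessel-wall annulus with a concentric intensity
gradient, a dim background, and multiplicative speckle whose amplitude
follows a Rayleigh distribution.  Geometry is exact, so every frame
comes with a perfect lumen mask — the ground truth the real clinical
datasets provide by manual contouring.

The augmentation pipeline mirrors a standard training recipe for this
modality: Gaussian intensity noise (sigma 0.05 of the intensity range),
random rotation (+/-15 deg), horizontal/vertical flips, scaling in
[0.9, 1.1], translation of up to 10% of the frame, elastic deformation
(alpha 50, sigma 5) and brightness/contrast jitter.  Geometric
transforms are applied identically to image and mask; photometric ones
touch the image only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

# Rayleigh scale giving a unit-mean draw: E[Rayleigh(s)] = s*sqrt(pi/2)
RAYLEIGH_UNIT_MEAN_SCALE = float(np.sqrt(2.0 / np.pi))


class PhantomParameterError(ValueError):
    """A phantom parameter violates its invariant."""


@dataclasses.dataclass
class PhantomParams:
    """Generative parameters of one phantom frame.

    Intensities are in [0, 1]; lengths in pixels.  ``lumen_center`` of
    ``None`` means the geometric image center.  ``shadow_sector`` is an
    optional (start_angle_deg, width_deg) guidewire-shadow wedge.
    """

    image_size: int = 512
    lumen_center: tuple[float, float] | None = None
    lumen_radius: float = 40.0
    wall_thickness: float = 30.0
    wall_peak_intensity: float = 0.85
    lumen_intensity: float = 0.05
    speckle_scale: float = 1.0
    shadow_sector: tuple[float, float] | None = None
    background_intensity: float = 0.12

    def center(self) -> tuple[float, float]:
        if self.lumen_center is None:
            c = (self.image_size - 1) / 2.0
            return (c, c)
        return tuple(self.lumen_center)

    def validate(self) -> None:
        if self.image_size < 8:
            raise PhantomParameterError("image_size must be at least 8")
        if self.lumen_radius <= 0 or self.wall_thickness <= 0:
            raise PhantomParameterError("lumen_radius and wall_thickness must be positive")
        if self.lumen_radius + self.wall_thickness >= self.image_size / 2:
            raise PhantomParameterError(
                "lumen_radius + wall_thickness must be < image_size/2")
        for name in ("wall_peak_intensity", "lumen_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PhantomParameterError(f"{name} must be in [0, 1], got {v}")
        if self.lumen_intensity >= self.wall_peak_intensity:
            raise PhantomParameterError("lumen_intensity must be < wall_peak_intensity")
        if self.speckle_scale < 0:
            raise PhantomParameterError("speckle_scale must be non-negative")


@dataclasses.dataclass
class AugmentConfig:
    """Per-transform limits and application probabilities."""

    gaussian_sigma: float = 0.05
    rotation_limit: float = 15.0
    flip_horizontal: bool = True
    flip_vertical: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.10
    elastic_alpha: float = 50.0
    elastic_sigma: float = 5.0
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    contrast_range: tuple[float, float] = (0.9, 1.1)
    apply_prob: float = 0.5

    def validate(self) -> None:
        if min(self.gaussian_sigma, self.rotation_limit, self.translate_frac,
               self.elastic_alpha, self.elastic_sigma) < 0:
            raise ValueError("augmentation limits must be non-negative")
        if not (self.scale_range[0] <= 1.0 <= self.scale_range[1]):
            raise ValueError("scale_range must bracket 1.0")
        if not (0.0 <= self.apply_prob <= 1.0):
            raise ValueError("apply_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# frame synthesis

def radial_profile(dist: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Noise-free intensity as a function of distance from the lumen center.

    Piecewise: lumen plateau, linear ramp to the wall peak at
    ``lumen_radius + wall_thickness/2``, then exponential decay toward the
    background level with decay length ``wall_thickness/2`` — a dark lumen
    inside a bright concentric annulus.
    """
    R = params.lumen_radius
    half_w = params.wall_thickness / 2.0
    peak_r = R + half_w
    out = np.empty_like(dist, dtype=np.float64)

    lum = dist <= R
    ramp = (dist > R) & (dist <= peak_r)
    tail = dist > peak_r
    out[lum] = params.lumen_intensity
    t = (dist[ramp] - R) / half_w
    out[ramp] = params.lumen_intensity + t * (params.wall_peak_intensity - params.lumen_intensity)
    decay = np.exp(-(dist[tail] - peak_r) / half_w)
    out[tail] = params.background_intensity + \
        (params.wall_peak_intensity - params.background_intensity) * decay
    return out


def apply_speckle(image: np.ndarray, scale: float, seed: int) -> np.ndarray:
    """Multiply by unit-mean Rayleigh speckle of strength ``scale``.

    The multiplier is ``1 + scale*(R - 1)`` with ``R`` i.i.d. Rayleigh
    draws normalized to unit mean, so the expected brightness is
    speckle-invariant at every strength; ``scale=1`` (default) is the pure
    unit-mean Rayleigh multiplier and ``scale=0`` is the identity.  Output
    is clipped to [0, 1].
    """
    if scale < 0:
        raise ValueError("speckle scale must be non-negative")
    image = np.asarray(image, dtype=np.float64)
    if scale == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    r = rng.rayleigh(scale=RAYLEIGH_UNIT_MEAN_SCALE, size=image.shape)
    mult = 1.0 + scale * (r - 1.0)
    return np.clip(image * mult, 0.0, 1.0)


def generate_phantom(params: PhantomParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom frame and its exact lumen mask.

    Returns ``(image, mask)`` — float64 intensities in [0, 1] and a uint8
    {0, 1} disk mask.  Identical ``(params, seed)`` give bit-identical
    output; the mask depends on geometry only, never on the seed.
    """
    params.validate()
    n = params.image_size
    cx, cy = params.center()
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(xx - cx, yy - cy)
    image = radial_profile(dist, params)

    if params.shadow_sector is not None:
        start, width = params.shadow_sector
        ang = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        in_sector = ((ang - start) % 360.0) < width
        outside_lumen = dist > params.lumen_radius
        image = np.where(in_sector & outside_lumen, image * 0.25, image)

    image = apply_speckle(image, params.speckle_scale, seed)
    mask = (dist <= params.lumen_radius).astype(np.uint8)
    return image, mask


# ---------------------------------------------------------------------------
# augmentations (each helper is deterministic given its arguments)

def rotate_pair(image: np.ndarray, mask: np.ndarray, angle_deg: float):
    img = ndimage.rotate(image, angle_deg, reshape=False, order=1, mode="nearest")
    msk = ndimage.rotate(mask.astype(np.uint8), angle_deg, reshape=False, order=0,
                         mode="constant", cval=0)
    return img, (msk > 0).astype(np.uint8)


def scale_translate_pair(image: np.ndarray, mask: np.ndarray, scale: float,
                         shift: tuple[float, float]):
    """Zoom about the image center by ``scale`` then shift by (dy, dx) px."""
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.eye(2) / scale
    offset = center - matrix @ (center + np.asarray(shift))
    img = ndimage.affine_transform(image, matrix, offset=offset, order=1, mode="nearest")
    msk = ndimage.affine_transform(mask.astype(np.uint8), matrix, offset=offset,
                                   order=0, mode="constant", cval=0)
    return img, (msk > 0).astype(np.uint8)


def elastic_pair(image: np.ndarray, mask: np.ndarray, alpha: float, sigma: float,
                 rng: np.random.Generator):
    """Smooth random displacement field (magnitude alpha, smoothness sigma)."""
    h, w = image.shape
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy + dy, xx + dx])
    img = ndimage.map_coordinates(image, coords, order=1, mode="reflect")
    msk = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0, mode="constant",
                                  cval=0)
    return img, (msk > 0).astype(np.uint8)


def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Randomly augment an image/mask pair; masks stay binary.

    Each transform fires independently with ``cfg.apply_prob``; parameter
    draws happen whether or not a transform fires, so the random stream is
    identical across configs and runs with the same seed.
    """
    cfg.validate()
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64).copy()
    msk = np.asarray(mask).astype(np.uint8).copy()

    p = cfg.apply_prob

    fire = rng.random() < p
    angle = rng.uniform(-cfg.rotation_limit, cfg.rotation_limit)
    if fire and angle != 0.0:
        img, msk = rotate_pair(img, msk, angle)

    if cfg.flip_horizontal and rng.random() < p:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if cfg.flip_vertical and rng.random() < p:
        img, msk = img[::-1, :].copy(), msk[::-1, :].copy()

    fire = rng.random() < p
    scale = rng.uniform(*cfg.scale_range)
    shift = rng.uniform(-cfg.translate_frac, cfg.translate_frac, size=2) * img.shape
    if fire:
        img, msk = scale_translate_pair(img, msk, scale, tuple(shift))

    fire = rng.random() < p
    elastic_rng = np.random.default_rng(rng.integers(2 ** 31))
    if fire and cfg.elastic_alpha > 0:
        img, msk = elastic_pair(img, msk, cfg.elastic_alpha, cfg.elastic_sigma, elastic_rng)

    fire = rng.random() < p
    noise = rng.normal(0.0, cfg.gaussian_sigma, size=img.shape)
    if fire and cfg.gaussian_sigma > 0:
        img = img + noise

    fire = rng.random() < p
    contrast = rng.uniform(*cfg.contrast_range)
    brightness = rng.uniform(*cfg.brightness_range)
    if fire:
        img = (img - 0.5) * contrast + 0.5 + brightness

    return np.clip(img, 0.0, 1.0), msk


# ---------------------------------------------------------------------------
# dataset synthesis

#: Per-frame parameter ranges (fractions of image size where geometric).
#: The radius band keeps the lumen between ~1.1% and ~2.8% of the frame
#: area, inside the modality's stated <3% envelope.
DEFAULT_PARAM_RANGES: dict = {
    "lumen_radius_frac": (0.060, 0.095),
    "wall_thickness_frac": (0.040, 0.080),
    "center_jitter_frac": 0.05,
    "lumen_intensity": (0.02, 0.10),
    "wall_peak_intensity": (0.70, 0.95),
    "background_intensity": (0.08, 0.18),
    "speckle_scale": (0.8, 1.0),
}


def sample_params(image_size: int, rng: np.random.Generator,
                  ranges: dict | None = None) -> PhantomParams:
    """Draw one frame's parameters from (possibly overridden) ranges."""
    r = dict(DEFAULT_PARAM_RANGES)
    if ranges:
        r.update(ranges)
    c = (image_size - 1) / 2.0
    jitter = r["center_jitter_frac"] * image_size
    center = (c + rng.uniform(-jitter, jitter), c + rng.uniform(-jitter, jitter))
    return PhantomParams(
        image_size=image_size,
        lumen_center=center,
        lumen_radius=rng.uniform(*r["lumen_radius_frac"]) * image_size,
        wall_thickness=rng.uniform(*r["wall_thickness_frac"]) * image_size,
        wall_peak_intensity=rng.uniform(*r["wall_peak_intensity"]),
        lumen_intensity=rng.uniform(*r["lumen_intensity"]),
        speckle_scale=rng.uniform(*r["speckle_scale"]),
        background_intensity=rng.uniform(*r["background_intensity"]),
    )


def save_png(path: Path, array01: np.ndarray) -> None:
    Image.fromarray(np.round(np.clip(array01, 0, 1) * 255).astype(np.uint8)).save(path)


def load_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0


def make_dataset(n_images: int, out_dir: str | Path, image_size: int = 512,
                 split: float = 0.8, seed: int = 0,
                 params_ranges: dict | None = None) -> dict:
    """Write ``n_images`` filename-matched image/mask PNG pairs plus a manifest.

    Split membership is by phantom identity (a deterministic shuffle of
    frame indices under ``seed``); the manifest records each frame's seed
    and generative parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_train = int(round(n_images * split))
    order = rng.permutation(n_images)
    split_of = {int(idx): ("train" if k < n_train else "val")
                for k, idx in enumerate(order)}

    entries = []
    for i in range(n_images):
        params = sample_params(image_size, rng, params_ranges)
        frame_seed = int(rng.integers(2 ** 31))
        image, mask = generate_phantom(params, frame_seed)
        img_name = f"case_{i:04d}.png"
        msk_name = f"case_{i:04d}_mask.png"
        save_png(out_dir / img_name, image)
        save_png(out_dir / msk_name, mask.astype(np.float64))
        rec = dataclasses.asdict(params)
        entries.append({
            "image": img_name,
            "mask": msk_name,
            "split": split_of[i],
            "seed": frame_seed,
            "subject": i,  # one phantom identity per frame
            "params": rec,
        })

    manifest = {"n_images": n_images, "image_size": image_size, "split": split,
                "seed": seed, "entries": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "manifest.json") as fh:
        return json.load(fh)
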