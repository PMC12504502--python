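"""Image/mask I/O, foreground-background decomposition, synthetic fixtures.

Conventions
-----------
Arrays are channel-first ``[C, row, col]`` float64. Images live in [0, 1];
masks are single-channel ``[1, H, W]`` with values exactly {0, 1}
(foreground = 1). A lesion image ``I`` with binary mask ``M`` decomposes as

    I_fore = I * M,   I_back = I * (1 - M),

so ``I_fore + I_back == I`` exactly — the reconstruction branch trains one
decoder per term.

The fixture generator emulates dermoscopy/histology-style data at desk
scale: blob-shaped lesions with wobbly elliptical outlines, smooth textured
background, optional boundary blur, additive noise and optional dark
hair-like strokes. Everything is driven by one integer seed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageSample",
    "Decomposition",
    "FixtureSpec",
    "load_sample",
    "decompose",
    "generate_fixtures",
    "write_prediction",
    "load_mask",
    "write_sample",
    "load_dataset",
    "write_dataset",
]


@dataclass
class ImageSample:
    """One RGB image with its binary segmentation mask."""

    id: str
    image: np.ndarray  # [3, H, W] in [0, 1]
    mask: np.ndarray | None  # [1, H, W] in {0, 1}, or None when unlabeled
    source_size: tuple[int, int] = (0, 0)  # (height, width) before resize

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be [3,H,W], got {self.image.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.float64)
            if self.mask.shape != (1,) + self.image.shape[1:]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match image {self.image.shape}"
                )
            _require_binary(self.mask)


@dataclass
class Decomposition:
    """Foreground/background split of one image under its mask."""

    foreground: np.ndarray  # [3, H, W]
    background: np.ndarray  # [3, H, W]


def _require_binary(mask: np.ndarray) -> None:
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError(f"mask is not binary; found values {vals[:8]}")


def binarize(mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold to {0,1}. Idempotent on already-binary masks."""
    return (np.asarray(mask, dtype=np.float64) >= threshold).astype(np.float64)


def load_sample(image_path, mask_path, working_size: int = 256) -> ImageSample:
    """Load an image/mask pair, resize both to ``working_size`` square.

    The image is resized with bilinear interpolation and scaled to [0,1];
    the mask with nearest-neighbour and then thresholded at 0.5, so the
    result is exactly binary regardless of how the mask file was encoded
    (0/1, 0/255, or antialiased grays).
    """
    if working_size <= 0:
        raise ValueError("working_size must be positive")
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        with Image.open(image_path) as im:
            src_size = (im.height, im.width)
            im = im.convert("RGB").resize((working_size, working_size), Image.BILINEAR)
            img = np.asarray(im, dtype=np.float64) / 255.0
    except OSError as e:
        raise OSError(f"cannot read image file {image_path}: {e}") from e
    mask = load_mask(mask_path, working_size)
    if mask.sum() == 0:
        warnings.warn(f"mask {mask_path} has no foreground pixels", stacklevel=2)
    return ImageSample(
        id=image_path.stem,
        image=img.transpose(2, 0, 1),
        mask=mask,
        source_size=src_size,
    )


def load_mask(mask_path, working_size: int | None = None) -> np.ndarray:
    """Load a single-channel mask PNG as a binary [1,H,W] array."""
    mask_path = Path(mask_path)
    try:
        with Image.open(mask_path) as mm:
            mm = mm.convert("L")
            if working_size is not None:
                mm = mm.resize((working_size, working_size), Image.NEAREST)
            arr = np.asarray(mm, dtype=np.float64) / 255.0
    except OSError as e:
        raise OSError(f"cannot read mask file {mask_path}: {e}") from e
    return binarize(arr)[None, :, :]


def decompose(sample: ImageSample) -> Decomposition:
    """Split an image into foreground (mask==1) and background (mask==0)."""
    if sample.mask is None:
        raise ValueError("cannot decompose a sample without a mask")
    _require_binary(sample.mask)
    fore = sample.image * sample.mask
    back = sample.image * (1.0 - sample.mask)
    return Decomposition(foreground=fore, background=back)


def write_prediction(mask: np.ndarray, path) -> None:
    """Write a binary [1,H,W] (or [H,W]) mask as an 8-bit PNG (fg=255)."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim == 3:
        mask = mask[0]
    _require_binary(mask)
    path = Path(path)
    try:
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)
    except OSError as e:
        raise OSError(f"cannot write mask file {path}: {e}") from e


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a seeded batch of synthetic lesion images.

    ``contrast`` is the mean-intensity gap between lesion and surrounding
    tissue; ``blur_sigma`` softens the image (not the mask) across the
    lesion boundary, emulating the diffuse margins of dermoscopic lesions;
    ``hair_artifacts`` overlays dark curvilinear strokes like the hairs
    that commonly cross skin lesions.
    """

    n_samples: int = 8
    size: int = 64
    n_blobs: tuple[int, int] = (1, 2)
    blur_sigma: float = 1.5
    noise_sd: float = 0.02
    contrast: float = 0.35
    texture_amp: float = 0.06
    hair_artifacts: bool = False
    seed: int = 0


def _blob_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """One wobbly-ellipse blob support on a size x size grid."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = rng.uniform(0.3, 0.7) * size
    cx = rng.uniform(0.3, 0.7) * size
    a = rng.uniform(0.12, 0.28) * size
    b = rng.uniform(0.12, 0.28) * size
    theta0 = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    yr = dy * np.cos(theta0) - dx * np.sin(theta0)
    xr = dy * np.sin(theta0) + dx * np.cos(theta0)
    ang = np.arctan2(yr, xr)
    wobble = np.ones_like(ang)
    for k in range(2, 5):
        wobble += rng.uniform(0.0, 0.12) * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
    return ((yr / a) ** 2 + (xr / b) ** 2 <= wobble**2).astype(np.float64)


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean low-frequency texture field."""
    field_ = gaussian_filter(rng.standard_normal((size, size)), sigma, mode="wrap")
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _hair_strokes(rng: np.random.Generator, size: int, n: int) -> np.ndarray:
    """Binary support of thin sinusoidal strokes crossing the frame."""
    canvas = np.zeros((size, size))
    for _ in range(n):
        x0, x1 = sorted(rng.uniform(0, size, 2))
        y0 = rng.uniform(0, size)
        slope = rng.uniform(-1.0, 1.0)
        amp = rng.uniform(1.0, size / 8)
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        ts = np.linspace(0.0, 1.0, 4 * size)
        xs = x0 + ts * (x1 - x0 + 1e-9)
        ys = y0 + slope * (xs - x0) + amp * np.sin(2 * np.pi * freq * ts + phase)
        ix = np.clip(np.round(xs), 0, size - 1).astype(int)
        iy = np.clip(np.round(ys), 0, size - 1).astype(int)
        canvas[iy, ix] = 1.0
    return canvas


def generate_fixtures(spec: FixtureSpec) -> list[ImageSample]:
    """Generate ``spec.n_samples`` seeded image/mask pairs.

    Identical specs (including the seed) produce bit-identical samples; the
    generator owns its RNG stream and never touches numpy's global state.
    Every mask is guaranteed nonempty by construction (blob radii are
    bounded below and centers stay away from the border).
    """
    if spec.n_samples <= 0:
        raise ValueError("n_samples must be positive")
    lo, hi = spec.n_blobs
    if not (1 <= lo <= hi):
        raise ValueError("n_blobs range must satisfy 1 <= lo <= hi")
    size = spec.size
    samples = []
    for idx in range(spec.n_samples):
        # independent substreams so toggling distractors/noise leaves the
        # base image and mask of each sample untouched
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, idx, 0])))
        rng_hair = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, idx, 1])))
        rng_noise = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, idx, 2])))
        n_blobs = int(rng.integers(lo, hi + 1))
        mask = np.zeros((size, size))
        for _ in range(n_blobs):
            mask = np.maximum(mask, _blob_mask(rng, size))

        bg_level = rng.uniform(0.55, 0.75)
        fg_level = bg_level - spec.contrast
        # mild per-channel tint so the three channels are distinct but correlated
        tint = rng.uniform(-0.05, 0.05, size=3)
        bg_tex = _smooth_noise(rng, size, sigma=4.0) * spec.texture_amp
        fg_tex = _smooth_noise(rng, size, sigma=1.5) * spec.texture_amp

        if spec.blur_sigma > 0:
            alpha = gaussian_filter(mask, spec.blur_sigma)
        else:
            alpha = mask
        base = (bg_level + bg_tex) * (1.0 - alpha) + (fg_level + fg_tex) * alpha
        img = np.stack([np.clip(base + t, 0.0, 1.0) for t in tint])

        if spec.hair_artifacts:
            strokes = _hair_strokes(rng_hair, size, n=int(rng_hair.integers(2, 5)))
            img = img * (1.0 - 0.65 * strokes[None])

        if spec.noise_sd > 0:
            img = img + rng_noise.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        samples.append(
            ImageSample(
                id=f"fixture_{spec.seed}_{idx:03d}",
                image=img,
                mask=mask[None],
                source_size=(size, size),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# dataset directory layout: images/ + masks/ with matching stems
# ---------------------------------------------------------------------------


def write_sample(sample: ImageSample, images_dir, masks_dir) -> None:
    """Write one sample as 8-bit PNGs (quantizes image intensities)."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    arr = (np.clip(sample.image, 0, 1) * 255).round().astype(np.uint8).transpose(1, 2, 0)
    Image.fromarray(arr, mode="RGB").save(images_dir / f"{sample.id}.png")
    if sample.mask is not None:
        masks_dir.mkdir(parents=True, exist_ok=True)
        write_prediction(sample.mask, masks_dir / f"{sample.id}.png")


def write_dataset(samples: list[ImageSample], root) -> None:
    root = Path(root)
    for s in samples:
        write_sample(s, root / "images", root / "masks")
    with open(root / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "image", "mask"])
        for s in samples:
            w.writerow([s.id, f"images/{s.id}.png", f"masks/{s.id}.png"])


def load_dataset(root, working_size: int = 256) -> list[ImageSample]:
    """Load images/ + masks/ pairs (or a manifest.csv) under ``root``."""
    root = Path(root)
    manifest = root / "manifest.csv"
    pairs: list[tuple[Path, Path | None]] = []
    if manifest.exists():
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                mask = root / row["mask"] if row.get("mask") else None
                pairs.append((root / row["image"], mask))
    else:
        images_dir, masks_dir = root / "images", root / "masks"
        if not images_dir.is_dir():
            raise FileNotFoundError(f"no images/ directory under {root}")
        for img_path in sorted(images_dir.iterdir()):
            if img_path.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            mask_path = masks_dir / f"{img_path.stem}.png"
            pairs.append((img_path, mask_path if mask_path.exists() else None))
    samples = []
    for img_path, mask_path in pairs:
        if mask_path is None:
            with Image.open(img_path) as im:
                src = (im.height, im.width)
                im = im.convert("RGB").resize((working_size, working_size), Image.BILINEAR)
                img = np.asarray(im, dtype=np.float64) / 255.0
            samples.append(
                ImageSample(id=img_path.stem, image=img.transpose(2, 0, 1), mask=None,
                            source_size=src)
            )
        else:
            samples.append(load_sample(img_path, mask_path, working_size))
    if not samples:
        raise FileNotFoundError(f"no samples found under {root}")
    return samples
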