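"""Augmentation and standardization of foregrounds, backgrounds and
blended composites.

Foreground tools are zoomed, rotated, flipped and shifted — always
keeping every tool connected to the image border (transforms that break
the invariant are resampled, then the identity is used) — and receive
synthetic blood droplets and brightness jitter. Backgrounds get flips,
90° rotations, brightness changes, *flying distractors* (tool-shaped
cutouts of other backgrounds, blended with the same procedure as the real
tools and labelled background) and *endoscopic padding* (a black
rectangular or circular border with additive noise). Blended images get
photometric/occlusion augmentations (cutout, smoke, shadow, JPEG
compression, colour shifts, noise, blur); none of these ever modifies the
label. Finally both elements of a pair are resized to a standard width
(default 640 px, aspect preserved) and the taller one randomly cropped so
heights match.

Operation magnitudes are configurable; defaults are chosen to keep tools
recognizable.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Callable

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from .blending import BlendResult
from .types import (
    BackgroundSample,
    ContractError,
    ForegroundSample,
    ValidationError,
    as_image,
    as_mask,
)

__all__ = [
    "AugmentConfig",
    "augment_foreground",
    "augment_background",
    "add_flying_distractors",
    "add_endoscopic_padding",
    "augment_blended",
    "standardize_pair",
    "flip_horizontal",
    "rotate90",
]


@dataclass
class AugmentConfig:
    """Probabilities and magnitude ranges of every augmentation."""

    # foreground geometric
    p_zoom: float = 0.3
    zoom_range: tuple[float, float] = (0.7, 1.3)
    p_rotate: float = 0.3
    rotation_range: tuple[float, float] = (-90.0, 90.0)
    p_flip: float = 0.3
    p_shift: float = 0.3
    shift_fraction: float = 0.2
    max_retries: int = 10
    # foreground photometric
    p_brightness: float = 0.3
    brightness_delta: float = 0.2
    p_droplets: float = 0.3
    droplet_mean_count: float = 3.0
    droplet_radius: tuple[float, float] = (2.0, 15.0)
    droplet_alpha: tuple[float, float] = (0.3, 0.8)
    # background
    p_bg_flip: float = 0.3
    p_bg_rot90: float = 0.3
    p_bg_brightness: float = 0.3
    distractor_max: int = 3
    p_padding: float = 0.3
    pad_width_fraction: float = 0.1
    disc_radius_range: tuple[float, float] = (0.45, 0.55)
    pad_noise_sigma: float = 0.02
    # blended-image photometric (each applied independently with p_photo)
    p_photo: float = 0.3
    cutout_count: tuple[int, int] = (1, 3)
    cutout_size: tuple[int, int] = (8, 32)
    smoke_intensity: float = 0.35
    shadow_intensity: float = 0.35
    jpeg_quality: tuple[int, int] = (60, 100)
    noise_sigma: float = 0.03
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    standard_width: int = 640
    repad_after_blend: bool = False

    def __post_init__(self) -> None:
        probs = [
            self.p_zoom, self.p_rotate, self.p_flip, self.p_shift,
            self.p_brightness, self.p_droplets, self.p_bg_flip, self.p_bg_rot90,
            self.p_bg_brightness, self.p_padding, self.p_photo,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("augmentation probabilities must lie in [0, 1]")
        if self.standard_width < 64:
            raise ValidationError("standard width must be >= 64")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        """All probabilities zero: every augmentation is the identity."""
        return cls(
            p_zoom=0, p_rotate=0, p_flip=0, p_shift=0, p_brightness=0,
            p_droplets=0, p_bg_flip=0, p_bg_rot90=0, p_bg_brightness=0,
            p_padding=0, p_photo=0,
        )


# --- elementary transforms (exposed for the involution/group properties) ---

def flip_horizontal(image: np.ndarray) -> np.ndarray:
    return image[:, ::-1].copy()


def flip_vertical(image: np.ndarray) -> np.ndarray:
    return image[::-1, :].copy()


def rotate90(image: np.ndarray, k: int = 1) -> np.ndarray:
    return np.rot90(image, k=k, axes=(0, 1)).copy()


def _mask_components_touch_border(mask: np.ndarray) -> bool:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return False
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = set(np.unique(labels[border])) - {0}
    return len(touching) == n


def _geometric_fg(
    image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One random draw of the joint geometric transform (image bilinear,
    mask nearest + rebinarize)."""
    img, msk = image, mask.astype(np.float64)
    if rng.random() < cfg.p_flip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < cfg.p_flip:
        img, msk = img[::-1, :], msk[::-1, :]
    if rng.random() < cfg.p_zoom:
        z = rng.uniform(*cfg.zoom_range)
        h, w = mask.shape
        img = sktransform.rescale(img, z, order=1, channel_axis=2, mode="edge",
                                  anti_aliasing=False)
        msk = sktransform.rescale(msk, z, order=0, mode="constant", cval=0,
                                  anti_aliasing=False)
        img = _fit_to(img, (h, w), fill="edge")
        msk = _fit_to(msk, (h, w), fill="zero")
    if rng.random() < cfg.p_rotate:
        ang = rng.uniform(*cfg.rotation_range)
        img = ndimage.rotate(img, ang, axes=(0, 1), reshape=False, order=1,
                             mode="nearest")
        msk = ndimage.rotate(msk, ang, axes=(0, 1), reshape=False, order=0,
                             mode="constant", cval=0)
    if rng.random() < cfg.p_shift:
        h, w = mask.shape
        dy = rng.uniform(-cfg.shift_fraction, cfg.shift_fraction) * h
        dx = rng.uniform(-cfg.shift_fraction, cfg.shift_fraction) * w
        img = ndimage.shift(img, (dy, dx, 0), order=1, mode="nearest")
        msk = ndimage.shift(msk, (dy, dx), order=0, mode="constant", cval=0)
    img = np.clip(img, 0.0, 1.0)
    msk = (msk >= 0.5).astype(np.uint8)
    return img, msk


def _fit_to(arr: np.ndarray, shape: tuple[int, int], fill: str) -> np.ndarray:
    """Center-crop or pad ``arr`` to ``shape``."""
    h, w = arr.shape[:2]
    th, tw = shape
    # crop
    y0 = max(0, (h - th) // 2)
    x0 = max(0, (w - tw) // 2)
    arr = arr[y0 : y0 + th, x0 : x0 + tw]
    # pad
    ph, pw = th - arr.shape[0], tw - arr.shape[1]
    if ph > 0 or pw > 0:
        mode = "edge" if fill == "edge" else "constant"
        pad = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
        if arr.ndim == 3:
            pad = pad + ((0, 0),)
        arr = np.pad(arr, pad, mode=mode)
    return arr


def _draw_droplets(
    image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Blood droplets / tissue debris drawn strictly on tool pixels."""
    out = image.copy()
    n = rng.poisson(cfg.droplet_mean_count)
    if n == 0:
        return out
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return out
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        i = rng.integers(0, len(ys))
        cy, cx = ys[i], xs[i]
        r = rng.uniform(*cfg.droplet_radius)
        alpha = rng.uniform(*cfg.droplet_alpha)
        blob = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2
        blob &= mask.astype(bool)  # never touch non-tool pixels
        hue = (rng.uniform(-10.0, 10.0) % 360.0) / 360.0  # dark red ±10°
        rgb = skcolor.hsv2rgb(np.array([[[hue, 0.85, 0.35]]]))[0, 0]
        out[blob] = (1 - alpha) * out[blob] + alpha * rgb
    return out


def augment_foreground(
    fg: ForegroundSample, cfg: AugmentConfig, rng: np.random.Generator
) -> ForegroundSample:
    """Randomly transform a foreground, preserving border connectivity.

    Geometric draws violating the invariant (every component touching a
    border, mask nonempty) are resampled up to ``cfg.max_retries`` times;
    after that the geometric part falls back to the identity. Droplets and
    brightness are applied afterwards and cannot break the invariant.
    """
    img, msk = fg.image, fg.mask
    for _ in range(max(1, cfg.max_retries)):
        cand_img, cand_msk = _geometric_fg(fg.image, fg.mask, cfg, rng)
        if cand_msk.any() and _mask_components_touch_border(cand_msk):
            img, msk = cand_img, cand_msk
            break
    if rng.random() < cfg.p_droplets:
        img = _draw_droplets(img, msk, cfg, rng)
    if rng.random() < cfg.p_brightness:
        img = np.clip(img + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta), 0, 1)
    return ForegroundSample(image=img, mask=msk, id=fg.id)


def augment_background(
    bg: BackgroundSample, cfg: AugmentConfig, rng: np.random.Generator
) -> BackgroundSample:
    """Flips, 90° rotations and brightness jitter on a background."""
    img = bg.image
    if rng.random() < cfg.p_bg_flip:
        img = flip_horizontal(img)
    if rng.random() < cfg.p_bg_flip:
        img = flip_vertical(img)
    if rng.random() < cfg.p_bg_rot90 and img.shape[0] == img.shape[1]:
        img = rotate90(img, k=int(rng.integers(1, 4)))
    if rng.random() < cfg.p_bg_brightness:
        img = np.clip(img + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta), 0, 1)
    return BackgroundSample(image=img, id=bg.id)


BlendProcedure = Callable[[ForegroundSample, BackgroundSample], BlendResult]


def add_flying_distractors(
    bg: BackgroundSample,
    donor_bgs: list[BackgroundSample],
    shape_source: ForegroundSample,
    blend: BlendProcedure,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    count: int | None = None,
) -> BackgroundSample:
    """Blend tool-shaped cutouts of donor backgrounds into ``bg``.

    Each distractor takes a donor background's texture, cuts it with a
    randomly transformed copy of the shape source's tool mask, and blends
    it into the scene with the *same* blending procedure later used for
    the real tools — so blending artifacts stop being a foreground cue.
    Distractors contribute no label: they are background semantically.
    """
    if not donor_bgs:
        raise ContractError("at least one donor background is required")
    if not shape_source.mask.any():
        raise ContractError("shape source mask is empty")
    k = int(rng.integers(0, cfg.distractor_max + 1)) if count is None else count
    out = bg.image
    h, w = out.shape[:2]
    for _ in range(k):
        donor = donor_bgs[int(rng.integers(0, len(donor_bgs)))]
        shape = shape_source.mask.astype(np.float64)
        # random similarity transform of the tool shape
        ang = rng.uniform(0.0, 360.0)
        shape = ndimage.rotate(shape, ang, reshape=False, order=0, mode="constant")
        shape = np.roll(shape, (int(rng.integers(0, h)), int(rng.integers(0, w))), (0, 1))
        shape = _fit_to(shape, (h, w), fill="zero")
        shape_m = (shape >= 0.5).astype(np.uint8)
        if not shape_m.any():
            continue
        donor_img = _fit_to(donor.image, (h, w), fill="edge")
        pseudo_fg_img = donor_img
        # distractor = donor texture cut with the tool shape; blend() sees it
        # as a foreground sample but no label is kept
        try:
            pseudo = ForegroundSample.__new__(ForegroundSample)
            pseudo.image = as_image(pseudo_fg_img)
            pseudo.mask = as_mask(shape_m)
            pseudo.id = f"distractor-{donor.id}"
            result = blend(pseudo, BackgroundSample(image=out, id=bg.id))
        except ContractError:
            continue
        out = result.image
    return BackgroundSample(image=out, id=bg.id)


def add_endoscopic_padding(
    bg: BackgroundSample, cfg: AugmentConfig, rng: np.random.Generator
) -> BackgroundSample:
    """Simulate the black endoscope border: with probability ``p_padding``
    overlay a rectangular frame or the complement of a centered disc, set
    to black plus Gaussian noise. Image size is unchanged."""
    if rng.random() >= cfg.p_padding:
        return bg
    img = bg.image.copy()
    h, w = img.shape[:2]
    region = np.zeros((h, w), dtype=bool)
    if rng.random() < 0.5:  # rectangular frame
        wd = max(1, int(rng.uniform(0.02, cfg.pad_width_fraction) * min(h, w)))
        region[:wd, :] = region[-wd:, :] = True
        region[:, :wd] = region[:, -wd:] = True
    else:  # circular: everything outside a centered disc
        r = rng.uniform(*cfg.disc_radius_range) * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        region = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2) > r
    noise = np.abs(rng.normal(0.0, cfg.pad_noise_sigma, size=(h, w, 3)))
    img[region] = np.clip(noise, 0.0, 1.0)[region]
    return BackgroundSample(image=img, id=bg.id)


# --- photometric augmentations of blended images ---------------------------

def _jpeg_roundtrip(image: np.ndarray, quality: int) -> np.ndarray:
    buf = _io.BytesIO()
    arr = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    # 4:4:4 sampling: quality alone should control the loss
    PILImage.fromarray(arr).save(buf, format="JPEG", quality=int(quality), subsampling=0)
    buf.seek(0)
    out = np.asarray(PILImage.open(buf).convert("RGB"), dtype=np.float64) / 255.0
    return out


def apply_cutout(
    image: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig, fill: float = 0.0
) -> np.ndarray:
    """Fill random rectangles with a constant. The label is never updated,
    even where a cutout covers tool pixels (standard cutout semantics)."""
    out = image.copy()
    h, w = out.shape[:2]
    n = int(rng.integers(cfg.cutout_count[0], cfg.cutout_count[1] + 1))
    for _ in range(n):
        sh = int(rng.integers(cfg.cutout_size[0], cfg.cutout_size[1] + 1))
        sw = int(rng.integers(cfg.cutout_size[0], cfg.cutout_size[1] + 1))
        y0 = int(rng.integers(0, max(1, h - sh)))
        x0 = int(rng.integers(0, max(1, w - sw)))
        out[y0 : y0 + sh, x0 : x0 + sw] = fill
    return out


def _smoke(image: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    h, w = image.shape[:2]
    blob = ndimage.gaussian_filter(rng.random((h, w)), sigma=min(h, w) / 8.0)
    blob = (blob - blob.min()) / max(np.ptp(blob), 1e-9)
    a = cfg.smoke_intensity * blob[:, :, None]
    return np.clip((1 - a) * image + a * 0.9, 0.0, 1.0)


def _shadow(image: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    h, w = image.shape[:2]
    blob = ndimage.gaussian_filter(rng.random((h, w)), sigma=min(h, w) / 6.0)
    blob = (blob - blob.min()) / max(np.ptp(blob), 1e-9)
    return np.clip(image * (1.0 - cfg.shadow_intensity * blob[:, :, None]), 0.0, 1.0)


def _hsv_shift(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    hsv = skcolor.rgb2hsv(image)
    hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-0.05, 0.05)) % 1.0
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] + rng.uniform(-0.1, 0.1), 0, 1)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2] + rng.uniform(-0.1, 0.1), 0, 1)
    return np.clip(skcolor.hsv2rgb(hsv), 0.0, 1.0)


def _motion_blur(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    k = int(rng.integers(3, 8))
    horizontal = rng.random() < 0.5
    kern = np.ones(k) / k
    axis = 1 if horizontal else 0
    return np.stack(
        [ndimage.convolve1d(image[:, :, c], kern, axis=axis, mode="reflect")
         for c in range(3)],
        axis=-1,
    )


def augment_blended(
    image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Photometric/occlusion stack on a blended image; label untouched.

    Each operation is applied independently with probability
    ``cfg.p_photo``; output is clipped to [0, 1].
    """
    img = as_image(image)
    if rng.random() < cfg.p_photo:
        img = apply_cutout(img, rng, cfg)
    if rng.random() < cfg.p_photo:
        img = _smoke(img, rng, cfg)
    if rng.random() < cfg.p_photo:
        img = _shadow(img, rng, cfg)
    if rng.random() < cfg.p_photo:
        img = _jpeg_roundtrip(img, int(rng.integers(*cfg.jpeg_quality)))
    if rng.random() < cfg.p_photo:  # RGB shift
        img = np.clip(img + rng.uniform(-0.05, 0.05, size=3)[None, None, :], 0, 1)
    if rng.random() < cfg.p_photo:
        img = _hsv_shift(img, rng)
    if rng.random() < cfg.p_photo:  # additive Gaussian noise
        img = np.clip(img + rng.normal(0, cfg.noise_sigma, img.shape), 0, 1)
    if rng.random() < cfg.p_photo:  # multiplicative noise
        img = np.clip(img * (1.0 + rng.normal(0, cfg.noise_sigma, img.shape)), 0, 1)
    if rng.random() < cfg.p_photo:  # ISO-like: intensity-dependent noise
        img = np.clip(img + np.sqrt(np.maximum(img, 1e-6))
                      * rng.normal(0, cfg.noise_sigma, img.shape), 0, 1)
    if rng.random() < cfg.p_photo:  # Gaussian blur
        img = ndimage.gaussian_filter(img, (rng.uniform(*cfg.blur_sigma),) * 2 + (0,))
    if rng.random() < cfg.p_photo:
        img = _motion_blur(img, rng)
    if rng.random() < cfg.p_photo:  # median blur
        img = ndimage.median_filter(img, size=(3, 3, 1))
    return np.clip(img, 0.0, 1.0)


def _resize_to_width(
    image: np.ndarray, width: int, order: int
) -> np.ndarray:
    h, w = image.shape[:2]
    new_h = max(1, round(h * width / w))
    return sktransform.resize(
        image, (new_h, width), order=order, mode="edge", anti_aliasing=False
    )


def standardize_pair(
    fg: ForegroundSample,
    bg: BackgroundSample,
    width: int,
    rng: np.random.Generator,
) -> tuple[ForegroundSample, BackgroundSample]:
    """Resize both to the standard width and equalize heights.

    Aspect ratio is preserved (bilinear for images, nearest for masks,
    masks rebinarized at 0.5); the taller element is randomly cropped
    vertically so both display the same height, leaving the pair
    co-registered and ready to blend.
    """
    if fg.image.shape[1] < width // 4 or bg.image.shape[1] < width // 4:
        raise ContractError("inputs must be at least a quarter of the target width")
    fg_img = np.clip(_resize_to_width(fg.image, width, order=1), 0, 1)
    fg_msk = (_resize_to_width(fg.mask.astype(np.float64), width, order=0) >= 0.5).astype(np.uint8)
    bg_img = np.clip(_resize_to_width(bg.image, width, order=1), 0, 1)

    h_fg, h_bg = fg_img.shape[0], bg_img.shape[0]
    target = min(h_fg, h_bg)
    if h_fg > target:
        off = int(rng.integers(0, h_fg - target + 1))
        if not fg_msk[off : off + target].any():
            # never crop the tool away entirely: recenter on the mask rows
            rows = np.flatnonzero(fg_msk.any(axis=1))
            off = int(np.clip(rows[0], 0, h_fg - target))
        fg_img = fg_img[off : off + target]
        fg_msk = fg_msk[off : off + target]
    if h_bg > target:
        off = int(rng.integers(0, h_bg - target + 1))
        bg_img = bg_img[off : off + target]
    return (
        ForegroundSample(image=fg_img, mask=fg_msk, id=fg.id),
        BackgroundSample(image=bg_img, id=bg.id),
    )
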