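"""Procedural test fixtures: green-screen instrument images with exact
masks, tissue-like backgrounds, and corrupted probability maps.

These emulate a chroma-key recording session well enough to exercise every
pipeline stage without any external data: a green field with an
illumination gradient and sensor noise, one to three elongated metallic
shapes entering from the image border (with a soft shadow on the fabric,
deliberately excluded from the ground-truth mask), and red/pink
low-frequency tissue textures with specular highlights and a vignette.
Tool shapes are capsules rather than photoreal renders — correctness
claims downstream concern masks and blending arithmetic, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from .rng import make_rng
from .types import BackgroundSample, ForegroundSample, ValidationError, as_mask, as_probmap

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "make_foreground_fixture",
    "make_background_fixture",
    "make_probmap_fixture",
    "rgb_to_hsv_degrees",
    "green_band_fraction",
]

#: Default chroma band: hue 80–160° on the 0–360° wheel, S ≥ 0.25, V ≥ 0.15.
GREEN_BAND = (80.0, 160.0)
MIN_SATURATION = 0.25
MIN_VALUE = 0.15


class FixtureError(RuntimeError):
    """Procedural generation failed (e.g. tool placement retries exhausted)."""


@dataclass
class FixtureSpec:
    """Conditions of one emulated recording.

    n_tools is the number of instruments in frame (1–3, as in real
    chroma-key sessions); green_hue_center/spread describe the fabric
    colour in degrees; illumination_amplitude modulates a linear lighting
    gradient; noise_sigma is per-pixel Gaussian sensor noise.
    """

    n_tools: int = 2
    height: int = 128
    width: int = 128
    green_hue_center: float = 120.0
    green_hue_spread: float = 15.0
    illumination_amplitude: float = 0.15
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_tools <= 3:
            raise ValidationError("n_tools must lie in [1, 3]")
        if self.height < 64 or self.width < 64:
            raise ValidationError("fixture images must be at least 64×64")


def rgb_to_hsv_degrees(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (hue in degrees [0, 360), saturation, value) channels."""
    hsv = skcolor.rgb2hsv(image)
    return hsv[:, :, 0] * 360.0, hsv[:, :, 1], hsv[:, :, 2]


def green_band_fraction(
    image: np.ndarray,
    band: tuple[float, float] = GREEN_BAND,
    min_s: float = MIN_SATURATION,
    min_v: float = MIN_VALUE,
) -> float:
    """Fraction of pixels inside the chroma green band."""
    h, s, v = rgb_to_hsv_degrees(image)
    inside = (h >= band[0]) & (h <= band[1]) & (s >= min_s) & (v >= min_v)
    return float(inside.mean())


def _capsule_mask(
    shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, radius: float
) -> np.ndarray:
    """Pixels within ``radius`` of the segment p0–p1 (a stadium shape)."""
    hh, ww = shape
    yy, xx = np.mgrid[0:hh, 0:ww].astype(np.float64)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        t = np.zeros(shape)
    else:
        t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    cy = p0[0] + t * d[0]
    cx = p0[1] + t * d[1]
    dist = np.hypot(yy - cy, xx - cx)
    return dist <= radius


def _axis_coordinate(
    shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    hh, ww = shape
    yy, xx = np.mgrid[0:hh, 0:ww].astype(np.float64)
    d = p1 - p0
    denom = max(float(d @ d), 1e-12)
    return np.clip(((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / denom, 0.0, 1.0)


def _sample_capsule(
    rng: np.random.Generator, h: int, w: int, scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """A random capsule anchored slightly outside a random border edge.

    Direction scatters widely around the inward normal so several tools
    can share a frame without all converging on the centre; ``scale``
    shrinks length and radius when placement gets crowded.
    """
    side = rng.integers(0, 4)
    margin = 2.0
    if side == 0:  # top
        p0 = np.array([-margin, rng.uniform(0.15 * w, 0.85 * w)])
    elif side == 1:  # bottom
        p0 = np.array([h - 1 + margin, rng.uniform(0.15 * w, 0.85 * w)])
    elif side == 2:  # left
        p0 = np.array([rng.uniform(0.15 * h, 0.85 * h), -margin])
    else:  # right
        p0 = np.array([rng.uniform(0.15 * h, 0.85 * h), w - 1 + margin])
    center = np.array([h / 2.0, w / 2.0])
    direction = center - p0
    direction = direction / np.linalg.norm(direction)
    angle = rng.uniform(-1.0, 1.0)
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    direction = rot @ direction
    length = rng.uniform(0.3, 0.65) * min(h, w) * scale
    p1 = p0 + direction * length
    radius = rng.uniform(7.0, 11.0) * scale
    return p0, p1, radius


def make_foreground_fixture(spec: FixtureSpec) -> tuple[ForegroundSample, np.ndarray]:
    """Generate a green-screen instrument image with an exact mask.

    Returns the foreground sample and its ground-truth mask (the same
    array content; the mask is exact by construction, no extraction step
    is involved). Raises FixtureError if non-overlapping, border-connected
    tool placement fails after bounded retries.
    """
    rng = make_rng(spec.seed, "fixture-foreground")
    h, w = spec.height, spec.width

    # green field in HSV
    hue = np.full((h, w), spec.green_hue_center) + rng.normal(
        0.0, spec.green_hue_spread / 6.0, size=(h, w)
    )
    lo, hi = spec.green_hue_center - spec.green_hue_spread, spec.green_hue_center + spec.green_hue_spread
    hue = np.clip(hue, lo, hi)
    sat = np.clip(rng.uniform(0.6, 0.8) + rng.normal(0, 0.02, (h, w)), 0.4, 1.0)
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    grad = (np.cos(theta) * yy / h + np.sin(theta) * xx / w)
    grad = (grad - grad.min()) / max(np.ptp(grad), 1e-9) - 0.5
    val = np.clip(0.65 + spec.illumination_amplitude * grad, 0.3, 0.95)

    # place tools; each gets its own retry budget, shrinking the capsule
    # radius once placement gets crowded
    mask = np.zeros((h, w), dtype=bool)
    capsules = []
    for _tool in range(spec.n_tools):
        for attempt in range(150):
            scale = 1.0 if attempt < 50 else (0.75 if attempt < 100 else 0.55)
            p0, p1, radius = _sample_capsule(rng, h, w, scale=scale)
            cand = _capsule_mask((h, w), p0, p1, radius)
            if cand.sum() < 40 or not _touches(cand):
                continue
            # keep components separated by >= 3 px so the count stays exact
            grown = ndimage.binary_dilation(cand, iterations=3)
            if (grown & mask).any():
                continue
            mask |= cand
            capsules.append((p0, p1, radius, cand))
            break
        else:
            raise FixtureError(
                f"could not place {spec.n_tools} non-overlapping border-connected tools"
            )

    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    image = skcolor.hsv2rgb(hsv)

    # soft shadow on the fabric under each tool: darken value, keep hue/sat,
    # stay inside the chroma band (excluded from the ground-truth mask)
    shadow = np.zeros((h, w), dtype=np.float64)
    for p0, p1, radius, cand in capsules:
        sh = np.roll(np.roll(cand, 4, axis=0), 4, axis=1)
        shadow = np.maximum(shadow, ndimage.gaussian_filter(sh.astype(float), 2.0))
    shadow_strength = np.clip(shadow, 0, 1) * 0.25
    image *= (1.0 - shadow_strength[:, :, None])

    # metallic tool appearance: gray shaft with an axial brightness gradient
    # and a specular streak near the axis
    for p0, p1, radius, cand in capsules:
        t = _axis_coordinate((h, w), p0, p1)
        base = rng.uniform(0.5, 0.75)
        shade = np.clip(base + 0.25 * (t - 0.5), 0.25, 0.95)
        tint = rng.uniform(-0.03, 0.03, size=3)
        dist_axis = _capsule_mask((h, w), p0, p1, radius * 0.35)
        tool_rgb = shade[:, :, None] + tint[None, None, :]
        tool_rgb = tool_rgb + 0.18 * dist_axis[:, :, None]
        image[cand] = np.clip(tool_rgb, 0.0, 1.0)[cand]

    image = np.clip(image + rng.normal(0, spec.noise_sigma, image.shape), 0.0, 1.0)
    truth = as_mask(mask.astype(np.uint8))
    sample = ForegroundSample(image=image, mask=truth, id=f"fg-{spec.seed:06d}")
    return sample, truth.copy()


def _touches(component: np.ndarray) -> bool:
    return bool(
        component[0, :].any()
        or component[-1, :].any()
        or component[:, 0].any()
        or component[:, -1].any()
    )


# tissue palette anchors (dark red -> mid tissue -> pink highlight)
_TISSUE_STOPS = np.array(
    [[0.34, 0.05, 0.09], [0.62, 0.22, 0.26], [0.88, 0.56, 0.60]]
)


def _value_noise(rng: np.random.Generator, h: int, w: int, octaves: int = 4) -> np.ndarray:
    out = np.zeros((h, w))
    amp = 1.0
    total = 0.0
    for o in range(octaves):
        res = 4 * 2**o
        grid = rng.random((res, res))
        layer = sktransform.resize(grid, (h, w), order=3, mode="reflect", anti_aliasing=False)
        out += amp * layer
        total += amp
        amp *= 0.5
    out /= total
    out -= out.min()
    out /= max(np.ptp(out), 1e-9)
    return out


def make_background_fixture(spec: FixtureSpec) -> BackgroundSample:
    """Generate a tissue-like background: red/pink multi-octave texture
    with specular highlights and a dark vignette; essentially no pixels
    fall inside the chroma green band."""
    rng = make_rng(spec.seed, "fixture-background")
    h, w = spec.height, spec.width
    t = _value_noise(rng, h, w)

    # piecewise-linear palette lookup
    pos = t * (len(_TISSUE_STOPS) - 1)
    i0 = np.clip(pos.astype(int), 0, len(_TISSUE_STOPS) - 2)
    frac = (pos - i0)[:, :, None]
    image = _TISSUE_STOPS[i0] * (1 - frac) + _TISSUE_STOPS[i0 + 1] * frac

    # wet-tissue specular highlights: a few small bright desaturated blobs
    n_spec = rng.integers(2, 6)
    spots = np.zeros((h, w))
    for _ in range(n_spec):
        cy, cx = rng.uniform(0.1, 0.9) * h, rng.uniform(0.1, 0.9) * w
        r = rng.uniform(1.5, 4.0)
        yy, xx = np.mgrid[0:h, 0:w]
        spots = np.maximum(spots, np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2)))
    image = image + 0.55 * spots[:, :, None] * (1.0 - image)

    # vignette
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - h / 2, xx - w / 2) / (0.5 * np.hypot(h, w))
    image *= (1.0 - 0.35 * rr**2)[:, :, None]

    image = np.clip(image + rng.normal(0, spec.noise_sigma, image.shape), 0.0, 1.0)
    return BackgroundSample(image=image, id=f"bg-{spec.seed:06d}")


def make_probmap_fixture(
    truth: np.ndarray,
    flip_rate: float = 0.3,
    blur_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Corrupt a ground-truth mask into a plausible network probability map.

    The mask is Gaussian-blurred (boundary uncertainty), then a fraction
    ``flip_rate`` of pixels is pushed into the uncertain band (0.2, 0.8)
    uniformly at random, emulating a model that is confidently right in
    the bulk and unsure in scattered locations.
    """
    if not 0.0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5]")
    truth = as_mask(truth)
    rng = rng or np.random.default_rng(0)
    prob = truth.astype(np.float64)
    if blur_sigma > 0:
        prob = ndimage.gaussian_filter(prob, blur_sigma)
    if flip_rate > 0:
        push = rng.random(prob.shape) < flip_rate
        prob[push] = rng.uniform(0.2, 0.8, size=int(push.sum()))
    return as_probmap(np.clip(prob, 0.0, 1.0))
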