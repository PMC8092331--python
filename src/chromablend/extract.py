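"""Instrument extraction from chroma-key frames.

Stages: HSV green thresholding → keep the N_i largest connected
components (N_i = number of instruments in frame) → GrabCut refinement
seeded from the thresholded mask → automated quality heuristics. The
component filter runs before refinement: it is noise reduction on the
thresholded candidate, and the refined colour models should not be
poisoned by speckle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import grabcut as gc
from .fixtures import rgb_to_hsv_degrees
from .types import ContractError, ValidationError, as_image, as_mask

__all__ = [
    "ChromaConfig",
    "QCReport",
    "hsv_threshold",
    "keep_largest_components",
    "grabcut_refine_chroma",
    "qc_score",
    "extract_foreground",
]

_STRUCT8 = np.ones((3, 3), dtype=int)  # 8-connectivity


@dataclass
class ChromaConfig:
    """Chroma segmentation parameters.

    The hue band (degrees on a 0–360 wheel) plus minimum saturation and
    value define the *green set*; everything else is a tool candidate.
    Thresholds are tuned per recording session in practice — these
    defaults cover commodity green chroma fabric.
    """

    hue_low: float = 80.0
    hue_high: float = 160.0
    min_saturation: float = 0.25
    min_value: float = 0.15
    n_instruments: int = 1
    grabcut_iterations: int = 5
    sure_fg_erosion_radius: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_low < self.hue_high <= 360.0):
            raise ValidationError("hue band must satisfy 0 <= low < high <= 360")
        if self.n_instruments < 1:
            raise ValidationError("n_instruments must be >= 1")


def _green_set(image: np.ndarray, cfg: ChromaConfig) -> np.ndarray:
    h, s, v = rgb_to_hsv_degrees(image)
    return (
        (h >= cfg.hue_low)
        & (h <= cfg.hue_high)
        & (s >= cfg.min_saturation)
        & (v >= cfg.min_value)
    )


def hsv_threshold(image: np.ndarray, cfg: ChromaConfig) -> np.ndarray:
    """Candidate tool mask: the complement of the green chroma set."""
    image = as_image(image)
    return as_mask((~_green_set(image, cfg)).astype(np.uint8))


def keep_largest_components(mask: np.ndarray, n: int) -> np.ndarray:
    """Keep only the n largest 8-connected components.

    Area ties break toward the smaller label of a deterministic
    raster-scan labelling. With fewer than n components the mask is
    returned unchanged.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    mask = as_mask(mask)
    labels, ncomp = ndimage.label(mask, structure=_STRUCT8)
    if ncomp <= n:
        return mask.copy()
    areas = np.bincount(labels.ravel())[1:]  # label 1..ncomp
    # stable sort on negated area keeps smaller labels first among ties
    keep = np.argsort(-areas, kind="stable")[:n] + 1
    return as_mask(np.isin(labels, keep).astype(np.uint8))


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def grabcut_refine_chroma(
    image: np.ndarray,
    candidate: np.ndarray,
    cfg: ChromaConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Refine a thresholded candidate with GrabCut.

    Seeding: green-thresholded pixels are sure background; the candidate
    eroded by the configured radius is sure foreground (guards against
    halo pixels poisoning the foreground colour model); every remaining
    pixel is probable and re-decided by colour. Sure pixels keep their
    seeded class, always. An empty candidate yields an empty mask with a
    warning (no colour model can be fitted).
    """
    image = as_image(image)
    candidate = as_mask(candidate)
    if image.shape[:2] != candidate.shape:
        raise ContractError("image and candidate mask sizes differ")
    if not candidate.any():
        warnings.warn("empty candidate mask: no foreground to model", stacklevel=2)
        return np.zeros_like(candidate)

    green = _green_set(image, cfg)
    sure_fg = ndimage.binary_erosion(
        candidate.astype(bool), structure=_disk(cfg.sure_fg_erosion_radius), border_value=1
    )
    sure_fg &= ~green
    if not sure_fg.any():
        warnings.warn(
            "candidate vanished under erosion: returning the unrefined candidate",
            stacklevel=2,
        )
        return candidate.copy()

    trimap = np.full(candidate.shape, gc.TRIMAP_UNKNOWN, dtype=np.uint8)
    trimap[green] = gc.TRIMAP_BG
    trimap[sure_fg] = gc.TRIMAP_FG
    return gc.grabcut(
        image,
        trimap,
        init_fg=candidate.astype(bool),
        iterations=cfg.grabcut_iterations,
        rng=rng,
    )


@dataclass
class QCReport:
    """Automated surrogate for visual quality inspection of a mask."""

    flags: list[str] = field(default_factory=list)
    score: float = 1.0
    component_count: int = 0
    foreground_fraction: float = 0.0

    @property
    def passed(self) -> bool:
        return not self.flags


def qc_score(mask: np.ndarray, cfg: ChromaConfig) -> QCReport:
    """Flag masks whose component count, area or border contact is off.

    Flags: ``component_count`` (≠ N_i), ``foreground_fraction`` (outside
    [0.005, 0.8]) and ``border_contact`` (no component touches a border).
    score = 1 − flags/3. Failed masks are flagged, never dropped —
    exclusion is the caller's decision.
    """
    mask = as_mask(mask)
    labels, ncomp = ndimage.label(mask, structure=_STRUCT8)
    frac = float(mask.mean())
    flags: list[str] = []
    if ncomp != cfg.n_instruments:
        flags.append("component_count")
    if not 0.005 <= frac <= 0.8:
        flags.append("foreground_fraction")
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if not (mask.astype(bool) & border).any():
        flags.append("border_contact")
    return QCReport(
        flags=flags,
        score=1.0 - len(flags) / 3.0,
        component_count=int(ncomp),
        foreground_fraction=frac,
    )


def extract_foreground(
    image: np.ndarray,
    cfg: ChromaConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, QCReport]:
    """Full extraction pipeline: threshold → N_i components → GrabCut → QC."""
    candidate = hsv_threshold(image, cfg)
    filtered = keep_largest_components(candidate, cfg.n_instruments)
    refined = grabcut_refine_chroma(image, filtered, cfg, rng=rng)
    return refined, qc_score(refined, cfg)
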