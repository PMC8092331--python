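"""Core data types shared across the pipeline.

Images are carried internally as float64 arrays in [0, 1]; conversion to and
from 8-bit happens only at file boundaries (see :mod:`chromablend.io`).
Masks are H×W uint8 arrays over {0, 1} with 1 = tool/foreground, and are
always co-registered with their paired image (identical H×W, row-major,
origin at the top-left corner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ContractError",
    "ValidationError",
    "as_image",
    "as_mask",
    "as_probmap",
    "ForegroundSample",
    "BackgroundSample",
    "CompositeSample",
    "ManifestRecord",
    "DatasetManifest",
]


class ContractError(ValueError):
    """A precondition of an operation was violated (e.g. size mismatch)."""


class ValidationError(ValueError):
    """A data structure failed its internal consistency checks."""


MIN_IMAGE_SIDE = 8


def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return an RGB image array (H×W×3 float in [0, 1])."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H×W×3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < MIN_IMAGE_SIDE or arr.shape[1] < MIN_IMAGE_SIDE:
        raise ValidationError(f"image too small: {arr.shape[:2]}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError("image values must lie in [0, 1]")
    return arr


def as_mask(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a binary mask (H×W uint8 over {0, 1})."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValidationError(f"expected H×W mask, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError("mask values must be 0 or 1")
    return arr.astype(np.uint8)


def as_probmap(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a per-pixel probability map (H×W float in [0, 1])."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected H×W probability map, got shape {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError("probabilities must lie in [0, 1]")
    return arr


def _touches_border(component: np.ndarray) -> bool:
    return bool(
        component[0, :].any()
        or component[-1, :].any()
        or component[:, 0].any()
        or component[:, -1].any()
    )


@dataclass
class ForegroundSample:
    """An instrument image over chroma key plus its binary tool mask.

    Invariant: the mask is nonempty and every 8-connected foreground
    component touches at least one image border (instruments enter the
    frame from outside, they never float in the interior).
    """

    image: np.ndarray
    mask: np.ndarray
    id: str = "fg"

    def __post_init__(self) -> None:
        self.image = as_image(self.image)
        self.mask = as_mask(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValidationError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} differ"
            )
        if not self.mask.any():
            raise ValidationError("foreground mask is empty")
        from scipy import ndimage

        labels, n = ndimage.label(self.mask, structure=np.ones((3, 3), dtype=int))
        for lab in range(1, n + 1):
            if not _touches_border(labels == lab):
                raise ValidationError(
                    f"foreground component {lab} does not touch any image border"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class BackgroundSample:
    """A tool-free tissue image; its implicit label is all-background."""

    image: np.ndarray
    id: str = "bg"

    def __post_init__(self) -> None:
        self.image = as_image(self.image)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class CompositeSample:
    """A blended training image, its propagated label and full provenance.

    The label is always the (augmented) foreground mask — blending never
    touches it — so ``provenance`` is what distinguishes two composites of
    the same pair: foreground id, background id, blend mode or λ vector,
    draw index and seed.
    """

    image: np.ndarray
    label: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = as_image(self.image)
        self.label = as_mask(self.label)
        if self.image.shape[:2] != self.label.shape:
            raise ValidationError("composite image and label sizes differ")


@dataclass
class ManifestRecord:
    """Provenance of one composite: which sources, which blend, which seed."""

    composite_id: str
    fg_id: str
    bg_id: str
    blend: str | list[float]
    seed: int
    draw_index: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "composite_id": self.composite_id,
            "fg_id": self.fg_id,
            "bg_id": self.bg_id,
            "blend": self.blend,
            "seed": self.seed,
            "draw_index": self.draw_index,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ManifestRecord":
        return cls(
            composite_id=d["composite_id"],
            fg_id=d["fg_id"],
            bg_id=d["bg_id"],
            blend=d["blend"],
            seed=int(d["seed"]),
            draw_index=int(d.get("draw_index", 0)),
        )


FORMAT_VERSION = "1"


@dataclass
class DatasetManifest:
    """Index of a generated dataset: source counts plus per-sample records."""

    n_foregrounds: int
    n_backgrounds: int
    fg_ids: list[str] = field(default_factory=list)
    bg_ids: list[str] = field(default_factory=list)
    records: list[ManifestRecord] = field(default_factory=list)
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.n_foregrounds < 1 or self.n_backgrounds < 1:
            raise ValidationError("manifest requires at least one foreground and background")
        self.validate()

    def validate(self) -> None:
        ids = [r.composite_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate composite ids in manifest")
        fg_known = set(self.fg_ids)
        bg_known = set(self.bg_ids)
        for rec in self.records:
            if fg_known and rec.fg_id not in fg_known:
                raise ValidationError(f"record {rec.composite_id}: unknown fg id {rec.fg_id}")
            if bg_known and rec.bg_id not in bg_known:
                raise ValidationError(f"record {rec.composite_id}: unknown bg id {rec.bg_id}")
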