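"""Raster and manifest I/O.

File-boundary conventions:

* images: 8-bit PNG (write) / PNG or JPEG (read), rescaled to float [0, 1]
  in memory;
* binary masks: single-channel 8-bit PNG over {0, 255}; reading maps
  values > 127 to 1;
* probability maps: 32-bit float TIFF (PNG cannot hold floats);
* dataset manifests: JSON, round-trip exact, λ vectors at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import (
    DatasetManifest,
    ManifestRecord,
    as_image,
    as_mask,
    as_probmap,
)

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_probmap",
    "write_probmap",
    "read_manifest",
    "write_manifest",
]


class FormatError(ValueError):
    """File content is not in the expected raster/manifest format."""


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG raster as an H×W×3 float image in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise FormatError(f"cannot decode raster file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit channels, got {arr.dtype}")
    return as_image(arr.astype(np.float64) / 255.0)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float [0, 1] image as 8-bit PNG."""
    image = as_image(image)
    arr = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel {0, 255} PNG as a {0, 1} mask (>127 → 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot decode mask file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: masks must be single-channel, got shape {arr.shape}")
    return as_mask((arr > 127).astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0, 1} mask as a single-channel {0, 255} PNG."""
    mask = as_mask(mask)
    iio.imwrite(Path(path), (mask * 255).astype(np.uint8))


def read_probmap(path: str | Path) -> np.ndarray:
    """Read a 32-bit float TIFF probability map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot decode TIFF file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: probability maps must be single-channel")
    return as_probmap(np.asarray(arr, dtype=np.float64))


def write_probmap(prob: np.ndarray, path: str | Path) -> None:
    """Write a probability map as 32-bit float TIFF."""
    prob = as_probmap(prob)
    tifffile.imwrite(Path(path), prob.astype(np.float32))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Serialize a manifest to JSON (sorted keys, full float precision)."""
    manifest.validate()
    doc = {
        "format_version": manifest.format_version,
        "n_foregrounds": manifest.n_foregrounds,
        "n_backgrounds": manifest.n_backgrounds,
        "fg_ids": manifest.fg_ids,
        "bg_ids": manifest.bg_ids,
        "records": [r.to_dict() for r in manifest.records],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid manifest JSON: {exc}") from exc
    try:
        manifest = DatasetManifest(
            n_foregrounds=int(doc["n_foregrounds"]),
            n_backgrounds=int(doc["n_backgrounds"]),
            fg_ids=list(doc.get("fg_ids", [])),
            bg_ids=list(doc.get("bg_ids", [])),
            records=[ManifestRecord.from_dict(r) for r in doc.get("records", [])],
            format_version=str(doc.get("format_version", "1")),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: manifest missing field {exc}") from exc
    manifest.validate()
    return manifest
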