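"""Pipeline configuration: one YAML document drives every stage.

Every field has a default, so an empty config file (or none at all) is
valid. Sections map onto the stage configs: ``chroma`` →
:class:`~chromablend.extract.ChromaConfig`, ``blend`` →
:class:`~chromablend.blending.BlendSpec`, ``augment`` →
:class:`~chromablend.augment.AugmentConfig`, ``bands`` →
:class:`~chromablend.refine.CertaintyBands`; ``seed``, ``alpha`` and
``standard_width`` sit at the top level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .augment import AugmentConfig
from .blending import BlendSpec
from .extract import ChromaConfig
from .refine import CertaintyBands
from .types import ValidationError

__all__ = ["PipelineConfig", "load_config", "config_digest"]


@dataclass
class PipelineConfig:
    seed: int = 0
    alpha: tuple[float, ...] = (1.0, 1.0, 1.0)
    standard_width: int = 640
    chroma: ChromaConfig = field(default_factory=ChromaConfig)
    blend: BlendSpec = field(default_factory=BlendSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    bands: CertaintyBands = field(default_factory=CertaintyBands)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alpha):
            raise ValidationError("all alpha components must be strictly positive")
        if self.standard_width < 64:
            raise ValidationError("standard_width must be >= 64")


def _build(cls, data: dict[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Load a PipelineConfig from YAML; keyword overrides win over the file.

    ``path=None`` (or an empty file) yields the full-default config.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValidationError("config YAML must be a mapping")
        data = raw
    data.update({k: v for k, v in overrides.items() if v is not None})

    sections = {
        "chroma": ChromaConfig,
        "blend": BlendSpec,
        "augment": AugmentConfig,
        "bands": CertaintyBands,
    }
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in sections:
            kwargs[key] = value if dataclasses.is_dataclass(value) else _build(
                sections[key], dict(value)
            )
        else:
            kwargs[key] = tuple(value) if isinstance(value, list) else value
    return _build(PipelineConfig, kwargs)


def config_digest(cfg: PipelineConfig) -> str:
    """Stable hash of the effective configuration (for run reports)."""
    doc = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]
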