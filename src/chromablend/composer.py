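"""The sampling core: multi-blend enumeration, Dirichlet mix-blend,
the on-the-fly training sample stream, and precomputed-dataset generation.

*Multi-blend* emits one composite per basis function for every
foreground–background pair — M images per pair, identical labels.
*Mix-blend* instead draws a weight vector λ ~ Dir(α) per visit of a pair
and emits the single per-pixel convex combination Σ_m λ_m φ_m(x_f, x_b);
the default α = (1, 1, 1) is uniform over the simplex, while a tiny α
such as (0.001, 0.001, 0.001) concentrates draws at the simplex corners
and recovers multi-blend as a corner case. One fresh λ is drawn per
pair-visit (no caching), and pairs are sampled uniformly with
replacement, so the number of λ draws per pair grows with the number of
optimization steps.

Precomputation stores the M per-basis blends and one label per sample on
disk; the Dirichlet weighting is deferred to load time, which allows
infinite λ resampling from fixed disk content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .augment import (
    AugmentConfig,
    add_endoscopic_padding,
    add_flying_distractors,
    augment_background,
    augment_blended,
    augment_foreground,
    standardize_pair,
)
from .blending import (
    BASIS_ORDER,
    MODE_ALIASES as _MODE_ALIASES,
    BlendResult,
    BlendSpec,
    basis_blends,
    blend_by_name,
)
from .io import read_image, read_mask, write_image, write_manifest, write_mask
from .rng import make_rng
from .types import (
    BackgroundSample,
    CompositeSample,
    ContractError,
    DatasetManifest,
    ForegroundSample,
    ManifestRecord,
)

__all__ = [
    "MixWeights",
    "StreamConfig",
    "draw_mix_weights",
    "mix_blend",
    "multi_blend",
    "sample_stream",
    "precompute_dataset",
    "load_precomputed",
]


@dataclass
class MixWeights:
    """A Dirichlet draw λ over the blending basis, with its α."""

    lam: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=np.float64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.lam.shape != self.alpha.shape:
            raise ContractError("lambda and alpha must have equal length")
        if not np.all(self.lam > 0):
            raise ContractError("all mix weights must be strictly positive")
        if abs(float(self.lam.sum()) - 1.0) > 1e-9:
            raise ContractError("mix weights must sum to 1")


def draw_mix_weights(alpha, rng: np.random.Generator) -> MixWeights:
    """Draw λ ~ Dir(α); components strictly positive, summing to 1.

    Draws are floored at the smallest positive float and renormalised,
    guarding the strict-positivity invariant for very small α where the
    sampler can underflow a component to exactly zero.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.ndim != 1 or alpha.size < 1 or not np.all(alpha > 0):
        raise ContractError("alpha must be a vector of strictly positive reals")
    lam = rng.dirichlet(alpha)
    lam = np.maximum(lam, np.finfo(np.float64).tiny)
    lam = lam / lam.sum()
    return MixWeights(lam=lam, alpha=alpha)


def mix_blend(
    fg: ForegroundSample,
    bg: BackgroundSample,
    weights: MixWeights,
    spec: BlendSpec | None = None,
    basis: list[BlendResult] | None = None,
) -> CompositeSample:
    """Per-pixel convex combination of the basis blends: Σ_m λ_m φ_m.

    The label is the foreground mask, independent of λ. ``basis`` may be
    passed to reuse precomputed basis blends of the same pair.
    """
    if basis is None:
        basis = basis_blends(fg, bg, spec)
    if len(basis) != weights.lam.size:
        raise ContractError("|basis| must equal |lambda|")
    stack = np.stack([b.image for b in basis], axis=0)
    image = np.tensordot(weights.lam, stack, axes=(0, 0))
    return CompositeSample(
        image=np.clip(image, 0.0, 1.0),
        label=fg.mask.copy(),
        provenance={
            "fg_id": fg.id,
            "bg_id": bg.id,
            "lambda": [float(v) for v in weights.lam],
        },
    )


def multi_blend(
    fg: ForegroundSample, bg: BackgroundSample, spec: BlendSpec | None = None
) -> list[CompositeSample]:
    """One composite per basis function; labels are all identical."""
    out = []
    for mode, result in zip(BASIS_ORDER, basis_blends(fg, bg, spec)):
        out.append(
            CompositeSample(
                image=result.image,
                label=result.label,
                provenance={"fg_id": fg.id, "bg_id": bg.id, "blend": mode},
            )
        )
    return out


@dataclass
class StreamConfig:
    """Conditions of the on-the-fly training stream.

    ``mode`` selects the emitted blend: ``"mix"`` (default, a fresh
    Dirichlet-weighted sum per visit) or the name of a single basis
    function for the deterministic ablation modes.
    """

    n_iterations: int = 100
    alpha: tuple[float, ...] = (1.0, 1.0, 1.0)
    mode: str = "mix"
    blend: BlendSpec = field(default_factory=BlendSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    apply_augment: bool = True
    standard_width: int | None = None  # None: keep source size

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ContractError("n_iterations must be >= 1")
        if len(self.alpha) != len(BASIS_ORDER):
            raise ContractError("alpha must have one entry per basis function")
        if self.mode != "mix" and self.mode not in _MODE_ALIASES:
            raise ContractError(f"unknown stream mode {self.mode!r}")


def _stream_one(
    fgs: list[ForegroundSample],
    bgs: list[BackgroundSample],
    cfg: StreamConfig,
    streams: dict[str, np.random.Generator],
    draw_index: int,
) -> CompositeSample:
    rng_pair = streams["pair"]
    i = int(rng_pair.integers(0, len(fgs)))
    j = int(rng_pair.integers(0, len(bgs)))
    fg, bg = fgs[i], bgs[j]

    # λ first: flying distractors must use the same blending procedure —
    # under mix-blend, the λ-weighted sum itself — as the real tools
    mixing = cfg.mode == "mix"
    weights = draw_mix_weights(np.asarray(cfg.alpha), streams["lambda"])

    def blend_proc(f: ForegroundSample, b: BackgroundSample) -> BlendResult:
        if mixing:
            comp = mix_blend(f, b, weights, cfg.blend)
            return BlendResult(image=comp.image, label=comp.label)
        return blend_by_name(cfg.mode, f, b, cfg.blend)

    if cfg.apply_augment:
        fg = augment_foreground(fg, cfg.augment, streams["fg-aug"])
        bg = augment_background(bg, cfg.augment, streams["bg-aug"])
        donors = [b for k, b in enumerate(bgs) if k != j] or [bgs[j]]
        bg = add_flying_distractors(
            bg, donors, fg, blend_proc, cfg.augment, streams["placement"]
        )
        bg = add_endoscopic_padding(bg, cfg.augment, streams["bg-aug"])

    if cfg.standard_width is not None:
        fg, bg = standardize_pair(fg, bg, cfg.standard_width, streams["placement"])

    result = blend_proc(fg, bg)
    image = result.image
    if cfg.apply_augment:
        image = augment_blended(image, cfg.augment, streams["photo"])
    return CompositeSample(
        image=image,
        label=result.label,
        provenance={
            "fg_id": fg.id,
            "bg_id": bg.id,
            "blend": [float(v) for v in weights.lam] if mixing else cfg.mode,
            "draw_index": draw_index,
            "seed": cfg.seed,
        },
    )


def sample_stream(
    fgs: list[ForegroundSample],
    bgs: list[BackgroundSample],
    cfg: StreamConfig,
) -> Iterator[CompositeSample]:
    """On-the-fly mix-blend training stream.

    Each iteration samples a pair (i, j) uniformly with replacement,
    augments foreground and background (distractors and padding included,
    using the iteration's own λ-weighted blend), standardizes, blends the
    pair with every basis function, and emits the λ-weighted sum with its
    label. Fully determined by ``cfg.seed``.
    """
    if not fgs or not bgs:
        raise ContractError("foreground and background sets must be nonempty")
    streams = {
        name: make_rng(cfg.seed, name)
        for name in ("pair", "lambda", "fg-aug", "bg-aug", "placement", "photo")
    }
    for upsilon in range(cfg.n_iterations):
        yield _stream_one(fgs, bgs, cfg, streams, upsilon)


def precompute_dataset(
    fgs: list[ForegroundSample],
    bgs: list[BackgroundSample],
    n_samples: int,
    cfg: StreamConfig,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write n_samples × M per-basis blends plus labels and a manifest.

    Layout: ``<id>_<mode>.png`` per basis function, ``<id>_mask.png`` per
    sample, ``manifest.json`` at the root. The Dirichlet weighting is not
    baked in — apply it at read time with :func:`load_precomputed`.
    """
    if not fgs or not bgs:
        raise ContractError("foreground and background sets must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = {
        name: make_rng(cfg.seed, name)
        for name in ("pair", "lambda", "fg-aug", "bg-aug", "placement", "photo")
    }
    records = []
    for n in range(n_samples):
        rng_pair = streams["pair"]
        i = int(rng_pair.integers(0, len(fgs)))
        j = int(rng_pair.integers(0, len(bgs)))
        fg, bg = fgs[i], bgs[j]
        if cfg.apply_augment:
            fg = augment_foreground(fg, cfg.augment, streams["fg-aug"])
            bg = augment_background(bg, cfg.augment, streams["bg-aug"])
        if cfg.standard_width is not None:
            fg, bg = standardize_pair(fg, bg, cfg.standard_width, streams["placement"])
        sample_id = f"sample-{n:06d}"
        for mode, result in zip(BASIS_ORDER, basis_blends(fg, bg, cfg.blend)):
            write_image(result.image, out_dir / f"{sample_id}_{mode}.png")
        write_mask(fg.mask, out_dir / f"{sample_id}_mask.png")
        records.append(
            ManifestRecord(
                composite_id=sample_id,
                fg_id=fg.id,
                bg_id=bg.id,
                blend="precomputed-basis",
                seed=cfg.seed,
                draw_index=n,
            )
        )
    manifest = DatasetManifest(
        n_foregrounds=len(fgs),
        n_backgrounds=len(bgs),
        fg_ids=[f.id for f in fgs],
        bg_ids=[b.id for b in bgs],
        records=records,
    )
    write_manifest(manifest, out_dir / "manifest.json")
    return manifest


def load_precomputed(
    out_dir: str | Path,
    sample_id: str,
    alpha,
    rng: np.random.Generator,
) -> CompositeSample:
    """Load one precomputed sample and apply a fresh Dirichlet mix."""
    out_dir = Path(out_dir)
    images = [read_image(out_dir / f"{sample_id}_{mode}.png") for mode in BASIS_ORDER]
    label = read_mask(out_dir / f"{sample_id}_mask.png")
    weights = draw_mix_weights(alpha, rng)
    stack = np.stack(images, axis=0)
    image = np.clip(np.tensordot(weights.lam, stack, axes=(0, 0)), 0.0, 1.0)
    return CompositeSample(
        image=image,
        label=label,
        provenance={
            "sample_id": sample_id,
            "lambda": [float(v) for v in weights.lam],
        },
    )
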