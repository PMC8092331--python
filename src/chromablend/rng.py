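"""Seeded-randomness contract.

One global seed fans out into named, mutually independent substreams
("fg-aug", "bg-aug", "lambda", "placement", ...). Adding a new consumer
with a new label never perturbs the draw sequence of existing labels, so
pipelines stay byte-reproducible as they grow.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["make_rng", "stream_seed"]


def _label_key(label: str) -> int:
    # crc32 is stable across runs and platforms (unlike builtin hash()).
    return zlib.crc32(label.encode("utf-8"))


def stream_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Derive the SeedSequence of the named substream of ``seed``."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(_label_key(label),))


def make_rng(seed: int, label: str = "") -> np.random.Generator:
    """Return a deterministic Generator for the (seed, label) substream.

    Same (seed, label) -> identical draw sequence; different label or
    different seed -> statistically independent streams.
    """
    return np.random.default_rng(stream_seed(seed, label))
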