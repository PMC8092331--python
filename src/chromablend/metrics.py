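"""Evaluation primitives: binarization, per-frame IoU, per-sequence mean,
and pixel-wise cross-entropy.

The IoU is epsilon-stabilized with the machine epsilon so that two empty
masks score 1 and every score lies in [0, 1]. The default denominator is
the Jaccard union |A ∪ B|; ``denominator="sum"`` keeps the alternative
Σŷ + Σy form (which halves the score of identical masks) available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ContractError, as_mask, as_probmap

__all__ = [
    "ScoreRecord",
    "SequenceScore",
    "binarize",
    "iou",
    "sequence_miou",
    "pixelwise_cross_entropy",
]

_EPS = float(np.finfo(np.float64).eps)
_PROB_FLOOR = 1e-12


@dataclass
class ScoreRecord:
    """Per-frame IoU J in [0, 1] plus bookkeeping."""

    J: float
    frame_id: str = ""
    n_pixels: int = 0
    epsilon: float = _EPS


@dataclass
class SequenceScore:
    """Arithmetic mean of per-frame scores; reported in percent."""

    records: list[ScoreRecord] = field(default_factory=list)
    mean_J: float = 0.0

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean_J


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (== threshold) go to foreground."""
    if not 0.0 <= threshold <= 1.0:
        raise ContractError("threshold must lie in [0, 1]")
    prob = as_probmap(prob)
    return as_mask((prob >= threshold).astype(np.uint8))


def iou(
    pred: np.ndarray,
    truth: np.ndarray,
    frame_id: str = "",
    denominator: str = "union",
) -> ScoreRecord:
    """Epsilon-stabilized intersection over union of two binary masks."""
    pred = as_mask(pred)
    truth = as_mask(truth)
    if pred.shape != truth.shape:
        raise ContractError(f"mask sizes differ: {pred.shape} vs {truth.shape}")
    inter = float(np.sum((pred == 1) & (truth == 1)))
    s_pred = float(pred.sum())
    s_truth = float(truth.sum())
    if denominator == "union":
        denom = s_pred + s_truth - inter
    elif denominator == "sum":
        denom = s_pred + s_truth
    else:
        raise ContractError("denominator must be 'union' or 'sum'")
    j = (inter + _EPS) / (denom + _EPS)
    return ScoreRecord(J=float(j), frame_id=frame_id, n_pixels=pred.size)


def sequence_miou(records: list[ScoreRecord]) -> SequenceScore:
    """Mean IoU across the frames of a sequence."""
    if not records:
        raise ContractError("cannot average an empty score list")
    mean = float(np.mean([r.J for r in records]))
    return SequenceScore(records=list(records), mean_J=mean)


def pixelwise_cross_entropy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Two-class pixel-wise cross-entropy (natural log, 1e-12 floor).

    ``pred`` is P(tool); P(background) = 1 − pred. Summed, not averaged,
    over all pixels.
    """
    pred = as_probmap(pred)
    truth = as_mask(truth)
    if pred.shape != truth.shape:
        raise ContractError("prediction and truth sizes differ")
    p = np.clip(pred, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    y = truth.astype(np.float64)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
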