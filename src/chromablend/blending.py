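"""The blending basis {φ_m}: trivial copy-paste, Gaussian feathering and
Laplacian pyramid blending.

All three operators take a foreground (instrument image + binary tool
mask) and a background of identical size and return a composited image
together with the label. The label is always the *binary* foreground
mask, unchanged — composited labels are obtained by keeping the
foreground labels irrespective of the blending function. That invariance
is what makes the basis mixable: any convex combination of basis outputs
shares the same ground truth.

Basis order is fixed to ``("trivial", "gaussian_feather", "laplacian")``;
Dirichlet mix weights index it positionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BackgroundSample, ContractError, ForegroundSample, as_mask

__all__ = [
    "BlendSpec",
    "BlendResult",
    "BASIS_ORDER",
    "blend_trivial",
    "blend_gaussian_feather",
    "blend_laplacian",
    "feather_soft_mask",
    "blend_by_name",
    "basis_blends",
]

BASIS_ORDER: tuple[str, ...] = ("trivial", "gaussian_feather", "laplacian")

#: CLI/config aliases for basis modes.
MODE_ALIASES = {
    "trivial": "trivial",
    "feather": "gaussian_feather",
    "gaussian_feather": "gaussian_feather",
    "laplacian": "laplacian",
}


@dataclass
class BlendSpec:
    """Parameters of the blending basis.

    erosion_kernel / blur_kernel are the odd square kernel sizes of the
    feathering stage (defaults 3 and 5); pyramid_levels is the Laplacian
    pyramid depth.
    """

    mode: str = "trivial"
    erosion_kernel: int = 3
    blur_kernel: int = 5
    pyramid_levels: int = 4

    def __post_init__(self) -> None:
        if self.mode not in MODE_ALIASES:
            raise ContractError(f"unknown blend mode {self.mode!r}")
        self.mode = MODE_ALIASES[self.mode]
        for k in (self.erosion_kernel, self.blur_kernel):
            if k < 1 or k % 2 == 0:
                raise ContractError("kernel sizes must be odd and >= 1")
        if self.pyramid_levels < 1:
            raise ContractError("pyramid_levels must be >= 1")


@dataclass
class BlendResult:
    image: np.ndarray
    label: np.ndarray


def _check_sizes(fg: ForegroundSample, bg: BackgroundSample) -> None:
    if fg.image.shape != bg.image.shape:
        raise ContractError(
            f"foreground {fg.image.shape} and background {bg.image.shape} sizes differ"
        )


def blend_trivial(fg: ForegroundSample, bg: BackgroundSample) -> BlendResult:
    """Copy-paste: tool pixels from the foreground, the rest from the background."""
    _check_sizes(fg, bg)
    m = fg.mask.astype(bool)
    out = bg.image.copy()
    out[m] = fg.image[m]
    return BlendResult(image=out, label=fg.mask.copy())


def _gaussian_kernel1d(ksize: int) -> np.ndarray:
    # The conventional kernel-size-to-sigma rule for a ksize-tap Gaussian.
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    r = (ksize - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _sep_convolve(arr: np.ndarray, k: np.ndarray) -> np.ndarray:
    out = ndimage.convolve1d(arr, k, axis=0, mode="reflect")
    return ndimage.convolve1d(out, k, axis=1, mode="reflect")


def feather_soft_mask(mask: np.ndarray, spec: BlendSpec | None = None) -> np.ndarray:
    """Soft mask m = GaussianBlur(Erode(y_f, k_e), k_b), values in [0, 1].

    Erosion uses a k_e×k_e square structuring element with the outside of
    the frame treated as foreground, so a mask that fills the frame stays
    all-ones. The blur kernel is the explicit k_b-tap separable Gaussian.
    """
    spec = spec or BlendSpec(mode="gaussian_feather")
    mask = as_mask(mask)
    ke = spec.erosion_kernel
    eroded = ndimage.binary_erosion(
        mask.astype(bool), structure=np.ones((ke, ke), dtype=bool), border_value=1
    ).astype(np.float64)
    soft = _sep_convolve(eroded, _gaussian_kernel1d(spec.blur_kernel))
    return np.clip(soft, 0.0, 1.0)


def blend_gaussian_feather(
    fg: ForegroundSample, bg: BackgroundSample, spec: BlendSpec | None = None
) -> BlendResult:
    """Alpha blend with a feathered mask: I_G = m·x_f + (1−m)·x_b.

    The label stays the original binary mask, not the soft m.
    """
    _check_sizes(fg, bg)
    spec = spec or BlendSpec(mode="gaussian_feather")
    m = feather_soft_mask(fg.mask, spec)[:, :, None]
    out = m * fg.image + (1.0 - m) * bg.image
    return BlendResult(image=np.clip(out, 0.0, 1.0), label=fg.mask.copy())


# --- Laplacian pyramid machinery -------------------------------------------
# 5-tap binomial kernel (1,4,6,4,1)/16; reflect border handling; inputs are
# padded to a multiple of 2^levels and cropped after collapsing, so arbitrary
# sizes are supported and the collapse identity L + up(G) is exact in floats.

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _pyr_down(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        out = np.stack([_pyr_down(arr[:, :, c]) for c in range(arr.shape[2])], axis=-1)
        return out
    low = _sep_convolve(arr, _BINOMIAL5)
    return low[::2, ::2]


def _pyr_up(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if arr.ndim == 3:
        return np.stack(
            [_pyr_up(arr[:, :, c], shape) for c in range(arr.shape[2])], axis=-1
        )
    up = np.zeros(shape, dtype=np.float64)
    up[::2, ::2] = arr
    # doubled kernel restores unit DC gain after zero insertion
    out = ndimage.convolve1d(up, 2.0 * _BINOMIAL5, axis=0, mode="reflect")
    return ndimage.convolve1d(out, 2.0 * _BINOMIAL5, axis=1, mode="reflect")


def _gaussian_pyramid(arr: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [arr.astype(np.float64)]
    for _ in range(levels):
        pyr.append(_pyr_down(pyr[-1]))
    return pyr


def _laplacian_pyramid(arr: np.ndarray, levels: int) -> list[np.ndarray]:
    gauss = _gaussian_pyramid(arr, levels)
    lap = [
        gauss[i] - _pyr_up(gauss[i + 1], gauss[i].shape[:2]) for i in range(levels)
    ]
    lap.append(gauss[levels])  # low-pass residual
    return lap


def _collapse(lap: list[np.ndarray]) -> np.ndarray:
    out = lap[-1]
    for level in reversed(lap[:-1]):
        out = level + _pyr_up(out, level.shape[:2])
    return out


def _pad_to_multiple(arr: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape[:2]
    ph = (-h) % mult
    pw = (-w) % mult
    pad = ((0, ph), (0, pw)) + (((0, 0),) if arr.ndim == 3 else ())
    return np.pad(arr, pad, mode="reflect"), (h, w)


def blend_laplacian(
    fg: ForegroundSample, bg: BackgroundSample, spec: BlendSpec | None = None
) -> BlendResult:
    """Multi-scale seam-free blend.

    Laplacian pyramids of both images are combined level-wise, weighted by
    the Gaussian pyramid of the mask, then collapsed and clipped to [0, 1].
    """
    _check_sizes(fg, bg)
    spec = spec or BlendSpec(mode="laplacian")
    L = spec.pyramid_levels
    h, w = fg.image.shape[:2]
    if h < 2**L or w < 2**L:
        raise ContractError(
            f"image {h}×{w} smaller than 2^levels = {2**L}; reduce pyramid_levels"
        )
    mult = 2**L
    xf, orig = _pad_to_multiple(fg.image, mult)
    xb, _ = _pad_to_multiple(bg.image, mult)
    m, _ = _pad_to_multiple(fg.mask.astype(np.float64), mult)

    lap_f = _laplacian_pyramid(xf, L)
    lap_b = _laplacian_pyramid(xb, L)
    gauss_m = _gaussian_pyramid(m, L)

    blended = [
        gm[:, :, None] * lf + (1.0 - gm[:, :, None]) * lb
        for gm, lf, lb in zip(gauss_m, lap_f, lap_b)
    ]
    out = _collapse(blended)[: orig[0], : orig[1]]
    return BlendResult(image=np.clip(out, 0.0, 1.0), label=fg.mask.copy())


def blend_by_name(
    mode: str, fg: ForegroundSample, bg: BackgroundSample, spec: BlendSpec | None = None
) -> BlendResult:
    mode = MODE_ALIASES.get(mode, mode)
    if mode == "trivial":
        return blend_trivial(fg, bg)
    if mode == "gaussian_feather":
        return blend_gaussian_feather(fg, bg, spec)
    if mode == "laplacian":
        return blend_laplacian(fg, bg, spec)
    raise ContractError(f"unknown blend mode {mode!r}")


def basis_blends(
    fg: ForegroundSample, bg: BackgroundSample, spec: BlendSpec | None = None
) -> list[BlendResult]:
    """Evaluate every basis function, in the fixed basis order."""
    return [blend_by_name(mode, fg, bg, spec) for mode in BASIS_ORDER]
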