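"""GrabCut-style segmentation: iterated Gaussian-mixture colour modelling
plus graph-cut energy minimization.

The solver works from a trimap: pixels marked *sure background* or *sure
foreground* are hard constraints and are never relabelled; only *unknown*
pixels enter the graph. Per iteration, one GMM per class is fitted to the
pixels currently carrying that class, the data term of every unknown pixel
is the negative log-likelihood under each mixture, and the pairwise term is
the standard contrast-sensitive Potts penalty

    w_ij = gamma / dist(i, j) * exp(-beta * ||z_i - z_j||^2)

with beta set to 1 / (2 <||z_i - z_j||^2>) over all 8-neighbour pairs. The
binary subproblem is solved exactly as a min-cut (scipy's max-flow on
integer-scaled capacities); sure-labelled neighbours of unknown pixels are
folded into the terminal capacities, which enforces the hard constraints by
construction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .types import ContractError

__all__ = ["TRIMAP_BG", "TRIMAP_FG", "TRIMAP_UNKNOWN", "grabcut"]

TRIMAP_BG = 0
TRIMAP_FG = 1
TRIMAP_UNKNOWN = 2

# integer scaling of float capacities for the max-flow solver
_CAP_SCALE = 256.0
_DATA_CLAMP = 60.0  # clamp on -log likelihood, in nats

# 8-neighbourhood offsets (forward half, each pair counted once)
_OFFSETS = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0)))


def _fit_gmm(pixels: np.ndarray, n_components: int, seed: int) -> GaussianMixture:
    n_components = int(min(n_components, max(1, len(np.unique(pixels, axis=0)))))
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=1e-4,
        max_iter=30,
        n_init=1,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # a loose colour model is fine: the cut only needs relative likelihoods
        warnings.simplefilter("ignore", ConvergenceWarning)
        gmm.fit(pixels)
    return gmm


def _pairwise_beta(image: np.ndarray) -> float:
    sq = 0.0
    count = 0
    for dy, dx, _ in _OFFSETS:
        diff = _shifted_diff(image, dy, dx)
        sq += float(diff.sum())
        count += diff.size
    mean = sq / max(count, 1)
    return 1.0 / (2.0 * mean) if mean > 0 else 0.0


def _shifted_diff(image: np.ndarray, dy: int, dx: int) -> np.ndarray:
    h, w = image.shape[:2]
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    yt = slice(max(0, dy), min(h, h + dy))
    xt = slice(max(0, dx), min(w, w + dx))
    d = image[ys, xs, :] - image[yt, xt, :]
    return np.sum(d * d, axis=-1)


def grabcut(
    image: np.ndarray,
    trimap: np.ndarray,
    init_fg: np.ndarray | None = None,
    iterations: int = 5,
    n_components: int = 5,
    gamma: float = 50.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Segment ``image`` under the hard constraints of ``trimap``.

    Parameters
    ----------
    image : H×W×3 float array in [0, 1].
    trimap : H×W int array over {TRIMAP_BG, TRIMAP_FG, TRIMAP_UNKNOWN}.
    init_fg : optional H×W bool array giving the initial foreground guess
        for unknown pixels (defaults to background everywhere).
    iterations : number of GMM-refit / min-cut rounds.
    n_components : mixture components per class.
    gamma : pairwise (edge) weight.
    rng : source of the GMM initialisation seeds (deterministic per call
        when provided).

    Returns
    -------
    H×W uint8 mask with 1 = foreground. Pixels marked sure in the trimap
    keep their trimap class, always.
    """
    if image.shape[:2] != trimap.shape:
        raise ContractError("image and trimap sizes differ")
    rng = rng or np.random.default_rng(0)
    h, w = trimap.shape
    unknown = trimap == TRIMAP_UNKNOWN

    alpha = trimap == TRIMAP_FG  # current fg labelling
    if init_fg is not None:
        alpha = alpha | (np.asarray(init_fg, dtype=bool) & unknown)

    if not unknown.any():
        return alpha.astype(np.uint8)
    if not (trimap == TRIMAP_FG).any() and not alpha.any():
        # no foreground evidence at all: nothing to model
        return alpha.astype(np.uint8)

    flat = image.reshape(-1, 3)
    beta = _pairwise_beta(image)

    # pairwise capacities, computed once
    idx = np.arange(h * w).reshape(h, w)
    pair_rows: list[np.ndarray] = []
    pair_cols: list[np.ndarray] = []
    pair_caps: list[np.ndarray] = []
    for dy, dx, dist in _OFFSETS:
        diff = _shifted_diff(image, dy, dx)
        wgt = (gamma / dist) * np.exp(-beta * diff)
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        yt = slice(max(0, dy), min(h, h + dy))
        xt = slice(max(0, dx), min(w, w + dx))
        pair_rows.append(idx[ys, xs].ravel())
        pair_cols.append(idx[yt, xt].ravel())
        pair_caps.append(wgt.ravel())
    prow = np.concatenate(pair_rows)
    pcol = np.concatenate(pair_cols)
    pcap = np.concatenate(pair_caps)

    unknown_flat = unknown.ravel()
    node_of = -np.ones(h * w, dtype=np.int64)
    unk_idx = np.flatnonzero(unknown_flat)
    node_of[unk_idx] = np.arange(unk_idx.size)
    n_nodes = unk_idx.size + 2
    source, sink = unk_idx.size, unk_idx.size + 1

    for _ in range(int(iterations)):
        fg_pix = flat[alpha.ravel()]
        bg_pix = flat[~alpha.ravel()]
        if len(fg_pix) == 0 or len(bg_pix) == 0:
            break
        gmm_fg = _fit_gmm(fg_pix, n_components, int(rng.integers(0, 2**31 - 1)))
        gmm_bg = _fit_gmm(bg_pix, n_components, int(rng.integers(0, 2**31 - 1)))

        z = flat[unk_idx]
        d_fg = np.clip(-gmm_fg.score_samples(z), 0.0, _DATA_CLAMP)
        d_bg = np.clip(-gmm_bg.score_samples(z), 0.0, _DATA_CLAMP)

        # terminal capacities: source(=fg side)→i pays when i is cut to bg,
        # so cap(source→i) = D_bg(i);  cap(i→sink) = D_fg(i).
        cap_src = d_bg.copy()
        cap_snk = d_fg.copy()

        # fold pairwise edges touching sure pixels into terminal capacities
        both_unknown = unknown_flat[prow] & unknown_flat[pcol]
        for a, b in ((prow, pcol), (pcol, prow)):
            mask = unknown_flat[a] & ~unknown_flat[b]
            if mask.any():
                nodes = node_of[a[mask]]
                sure_fg = (trimap.ravel()[b[mask]] == TRIMAP_FG).astype(np.float64)
                np.add.at(cap_src, nodes, pcap[mask] * sure_fg)
                np.add.at(cap_snk, nodes, pcap[mask] * (1.0 - sure_fg))

        # assemble integer-capacity graph
        er = node_of[prow[both_unknown]]
        ec = node_of[pcol[both_unknown]]
        ew = np.rint(pcap[both_unknown] * _CAP_SCALE).astype(np.int64)
        rows = np.concatenate(
            [er, ec, np.full(unk_idx.size, source), np.arange(unk_idx.size)]
        )
        cols = np.concatenate(
            [ec, er, np.arange(unk_idx.size), np.full(unk_idx.size, sink)]
        )
        caps = np.concatenate(
            [
                ew,
                ew,
                np.rint(cap_src * _CAP_SCALE).astype(np.int64),
                np.rint(cap_snk * _CAP_SCALE).astype(np.int64),
            ]
        )
        graph = csr_matrix(
            (caps.astype(np.int32), (rows, cols)), shape=(n_nodes, n_nodes)
        )
        result = maximum_flow(graph, source, sink)
        residual = graph - result.flow
        residual.data = np.maximum(residual.data, 0)
        residual.eliminate_zeros()
        order = breadth_first_order(
            residual, source, directed=True, return_predecessors=False
        )
        fg_side = np.zeros(n_nodes, dtype=bool)
        fg_side[order] = True

        new_alpha = alpha.copy().ravel()
        new_alpha[unk_idx] = fg_side[: unk_idx.size]
        new_alpha = new_alpha.reshape(h, w) | (trimap == TRIMAP_FG)
        new_alpha &= trimap != TRIMAP_BG
        if np.array_equal(new_alpha, alpha):
            alpha = new_alpha
            break
        alpha = new_alpha

    # hard constraints, re-asserted unconditionally
    alpha = alpha | (trimap == TRIMAP_FG)
    alpha = alpha & (trimap != TRIMAP_BG)
    return alpha.astype(np.uint8)
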