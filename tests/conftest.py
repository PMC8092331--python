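import numpy as np
import pytest

from chromablend import (
    BackgroundSample,
    FixtureSpec,
    ForegroundSample,
    make_background_fixture,
    make_foreground_fixture,
)


@pytest.fixture(scope="session")
def fg_sample() -> ForegroundSample:
    sample, _ = make_foreground_fixture(FixtureSpec(n_tools=2, seed=11))
    return sample


@pytest.fixture(scope="session")
def fg_truth() -> np.ndarray:
    _, truth = make_foreground_fixture(FixtureSpec(n_tools=2, seed=11))
    return truth


@pytest.fixture(scope="session")
def bg_sample() -> BackgroundSample:
    return make_background_fixture(FixtureSpec(seed=12))


@pytest.fixture(scope="session")
def fg_pool() -> list[ForegroundSample]:
    return [
        make_foreground_fixture(FixtureSpec(n_tools=1 + i % 3, seed=i))[0]
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def bg_pool() -> list[BackgroundSample]:
    return [make_background_fixture(FixtureSpec(seed=100 + i)) for i in range(5)]


def brute_force_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Independent set-counting oracle for the Jaccard index."""
    inter = 0
    union = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            pa, pb = a[i, j] == 1, b[i, j] == 1
            if pa and pb:
                inter += 1
            if pa or pb:
                union += 1
    eps = float(np.finfo(np.float64).eps)
    return (inter + eps) / (union + eps)


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Brute-force 8-connected component extraction (BFS, no scipy)."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                comp = set()
                stack = [(si, sj)]
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    comp.add((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (
                                0 <= ni < h
                                and 0 <= nj < w
                                and mask[ni, nj]
                                and not seen[ni, nj]
                            ):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                comps.append(comp)
    return comps
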