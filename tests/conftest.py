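"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
zone counting is a pure-Python flood fill, the separable wavelet oracle
uses ``np.convolve`` on mirror-padded arrays, and survival/agreement
oracles are hand computations.
"""

from collections import deque

import numpy as np
import pytest

from bcradiomics.image_io import ROIMask, Volume3D


def _offsets(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def glszm_bruteforce(arr: np.ndarray, connectivity: int = 26) -> dict:
    """Flood-fill zone counting: {(level, size): count}; 0 = background."""
    arr = np.asarray(arr)
    offs = _offsets(connectivity)
    visited = np.zeros(arr.shape, dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    for start in np.ndindex(arr.shape):
        if visited[start] or arr[start] == 0:
            continue
        level = int(arr[start])
        size = 0
        q = deque([start])
        visited[start] = True
        while q:
            cur = q.popleft()
            size += 1
            for off in offs:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nb, arr.shape)):
                    continue
                if not visited[nb] and arr[nb] == level:
                    visited[nb] = True
                    q.append(nb)
        counts[(level, size)] = counts.get((level, size), 0) + 1
    return counts


def glszm_to_dict(m) -> dict:
    """Convert a GLSZMatrix to the oracle's {(level, size): count} form."""
    out = {}
    for i in range(m.counts.shape[0]):
        for j in range(m.counts.shape[1]):
            if m.counts[i, j]:
                out[(i + 1, j + 1)] = int(m.counts[i, j])
    return out


def mask_from_array(arr, spacing=(1.0, 1.0, 1.0)) -> ROIMask:
    return ROIMask(np.asarray(arr, dtype=np.uint8), spacing=spacing)


def volume_from_array(arr, spacing=(1.0, 1.0, 1.0)) -> Volume3D:
    return Volume3D(np.asarray(arr, dtype=float), spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_volume(rng):
    return volume_from_array(rng.normal(size=(8, 8, 8)))
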