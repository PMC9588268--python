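"""Independent reference implementations used as oracles.

These deliberately avoid the package's code paths: the watershed oracle
is a plain heapq priority flood, and the median oracle gathers the 27
neighbors by hand.
"""

from __future__ import annotations

import heapq

import numpy as np

#: face-neighbor visiting order shared (by specification) with the package
OFFSETS = ((-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1))


def reference_watershed(image: np.ndarray, markers: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Priority-flood seeded watershed (pop by image value, then insertion age)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask, markers, 0).astype(np.int64)
    resolved = (out != 0) & mask
    nx, ny, nz = image.shape
    heap: list[tuple[float, int, tuple[int, int, int], int]] = []
    age = 0

    def push_neighbors(x: int, y: int, z: int, lab: int) -> None:
        nonlocal age
        for dx, dy, dz in OFFSETS:
            xn, yn, zn = x + dx, y + dy, z + dz
            if not (0 <= xn < nx and 0 <= yn < ny and 0 <= zn < nz):
                continue
            if not mask[xn, yn, zn] or resolved[xn, yn, zn]:
                continue
            heapq.heappush(heap, (image[xn, yn, zn], age, (xn, yn, zn), lab))
            age += 1

    for x, y, z in zip(*np.nonzero(resolved)):
        push_neighbors(int(x), int(y), int(z), int(out[x, y, z]))

    while heap:
        _, _, (x, y, z), lab = heapq.heappop(heap)
        if resolved[x, y, z]:
            continue
        resolved[x, y, z] = True
        out[x, y, z] = lab
        push_neighbors(x, y, z, lab)
    return out


def brute_force_median27(data: np.ndarray, x: int, y: int, z: int) -> float:
    """Median of the reflect-padded 3x3x3 neighborhood around one voxel."""
    padded = np.pad(data, 1, mode="symmetric")
    block = padded[x : x + 3, y : y + 3, z : z + 3]
    return float(np.median(block.ravel()))
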