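"""Deterministic seeded watershed by priority flooding.

The flood pops voxels from a min-heap keyed on (image value, insertion
age).  Ages are unique and increase in a fully specified order: marker
voxels seed the queue in raveled (lexicographic) order, and the six
face neighbors of each popped voxel are visited in the fixed order
(-x, +x, -y, +y, -z, +z).  Results are therefore bit-reproducible and
can be checked voxel-for-voxel against an independent reference
implementation of the same published rule.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["watershed", "NEIGHBOR_OFFSETS"]

#: fixed face-neighbor visiting order shared with the reference oracle
NEIGHBOR_OFFSETS = ((-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1))


@njit(cache=True)
def _flood(image, mask, output):  # pragma: no cover - exercised via watershed()
    nx, ny, nz = image.shape
    cap = 1024
    h_val = np.empty(cap, dtype=np.float64)
    h_age = np.empty(cap, dtype=np.int64)
    h_idx = np.empty(cap, dtype=np.int64)
    h_lab = np.empty(cap, dtype=np.int32)
    size = 0
    age = 0

    offs = np.empty((6, 3), dtype=np.int64)
    offs[0] = (-1, 0, 0)
    offs[1] = (1, 0, 0)
    offs[2] = (0, -1, 0)
    offs[3] = (0, 1, 0)
    offs[4] = (0, 0, -1)
    offs[5] = (0, 0, 1)

    resolved = np.zeros(image.shape, dtype=np.uint8)

    # seed: resolve markers, then enqueue their unlabeled in-mask neighbors
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if output[x, y, z] != 0 and mask[x, y, z]:
                    resolved[x, y, z] = 1

    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if resolved[x, y, z] == 0:
                    continue
                lab = output[x, y, z]
                for k in range(6):
                    xn = x + offs[k, 0]
                    yn = y + offs[k, 1]
                    zn = z + offs[k, 2]
                    if xn < 0 or xn >= nx or yn < 0 or yn >= ny or zn < 0 or zn >= nz:
                        continue
                    if not mask[xn, yn, zn] or resolved[xn, yn, zn] == 1:
                        continue
                    if size == cap:
                        cap *= 2
                        nv = np.empty(cap, dtype=np.float64)
                        na = np.empty(cap, dtype=np.int64)
                        ni = np.empty(cap, dtype=np.int64)
                        nl = np.empty(cap, dtype=np.int32)
                        nv[:size] = h_val[:size]
                        na[:size] = h_age[:size]
                        ni[:size] = h_idx[:size]
                        nl[:size] = h_lab[:size]
                        h_val, h_age, h_idx, h_lab = nv, na, ni, nl
                    # sift-up insert
                    i = size
                    size += 1
                    h_val[i] = image[xn, yn, zn]
                    h_age[i] = age
                    h_idx[i] = (xn * ny + yn) * nz + zn
                    h_lab[i] = lab
                    age += 1
                    while i > 0:
                        p = (i - 1) // 2
                        if h_val[p] > h_val[i] or (
                            h_val[p] == h_val[i] and h_age[p] > h_age[i]
                        ):
                            h_val[p], h_val[i] = h_val[i], h_val[p]
                            h_age[p], h_age[i] = h_age[i], h_age[p]
                            h_idx[p], h_idx[i] = h_idx[i], h_idx[p]
                            h_lab[p], h_lab[i] = h_lab[i], h_lab[p]
                            i = p
                        else:
                            break

    while size > 0:
        val = h_val[0]
        idx = h_idx[0]
        lab = h_lab[0]
        # pop root, sift-down
        size -= 1
        h_val[0] = h_val[size]
        h_age[0] = h_age[size]
        h_idx[0] = h_idx[size]
        h_lab[0] = h_lab[size]
        i = 0
        while True:
            left = 2 * i + 1
            right = left + 1
            smallest = i
            if left < size and (
                h_val[left] < h_val[smallest]
                or (h_val[left] == h_val[smallest] and h_age[left] < h_age[smallest])
            ):
                smallest = left
            if right < size and (
                h_val[right] < h_val[smallest]
                or (h_val[right] == h_val[smallest] and h_age[right] < h_age[smallest])
            ):
                smallest = right
            if smallest == i:
                break
            h_val[smallest], h_val[i] = h_val[i], h_val[smallest]
            h_age[smallest], h_age[i] = h_age[i], h_age[smallest]
            h_idx[smallest], h_idx[i] = h_idx[i], h_idx[smallest]
            h_lab[smallest], h_lab[i] = h_lab[i], h_lab[smallest]
            i = smallest

        z0 = idx % nz
        y0 = (idx // nz) % ny
        x0 = idx // (nz * ny)
        if resolved[x0, y0, z0] == 1:
            continue
        resolved[x0, y0, z0] = 1
        output[x0, y0, z0] = lab

        for k in range(6):
            xn = x0 + offs[k, 0]
            yn = y0 + offs[k, 1]
            zn = z0 + offs[k, 2]
            if xn < 0 or xn >= nx or yn < 0 or yn >= ny or zn < 0 or zn >= nz:
                continue
            if not mask[xn, yn, zn] or resolved[xn, yn, zn] == 1:
                continue
            if size == cap:
                cap *= 2
                nv = np.empty(cap, dtype=np.float64)
                na = np.empty(cap, dtype=np.int64)
                ni = np.empty(cap, dtype=np.int64)
                nl = np.empty(cap, dtype=np.int32)
                nv[:size] = h_val[:size]
                na[:size] = h_age[:size]
                ni[:size] = h_idx[:size]
                nl[:size] = h_lab[:size]
                h_val, h_age, h_idx, h_lab = nv, na, ni, nl
            i = size
            size += 1
            h_val[i] = image[xn, yn, zn]
            h_age[i] = age
            h_idx[i] = (xn * ny + yn) * nz + zn
            h_lab[i] = lab
            age += 1
            while i > 0:
                p = (i - 1) // 2
                if h_val[p] > h_val[i] or (
                    h_val[p] == h_val[i] and h_age[p] > h_age[i]
                ):
                    h_val[p], h_val[i] = h_val[i], h_val[p]
                    h_age[p], h_age[i] = h_age[i], h_age[p]
                    h_idx[p], h_idx[i] = h_idx[i], h_idx[p]
                    h_lab[p], h_lab[i] = h_lab[i], h_lab[p]
                    i = p
                else:
                    break
    return output


def watershed(image: np.ndarray, markers: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Seeded watershed: flood ``image`` uphill from labeled markers within ``mask``.

    Parameters
    ----------
    image : 3D float array
        Topography; lower values flood first (pass a negated distance map
        to split objects at their minimal cross-sections).
    markers : 3D int array
        Nonzero labels seed the flood; marker voxels keep their labels.
    mask : 3D bool array
        Voxels outside the mask stay 0.

    Returns
    -------
    3D int32 label array partitioning ``mask`` among the markers (voxels
    in mask components containing no marker remain 0).
    """
    image = np.ascontiguousarray(image, dtype=np.float64)
    mask = np.ascontiguousarray(mask, dtype=bool)
    if image.shape != markers.shape or image.shape != mask.shape:
        raise ValueError("image, markers and mask shapes must agree")
    output = np.where(mask, markers, 0).astype(np.int32)
    return _flood(image, mask, np.ascontiguousarray(output))
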