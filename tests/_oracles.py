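"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept separate from the package so
they never share code with the paths they check.
"""

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dz, dy, dx in product((-1, 0, 1), repeat=3):
        if (dz, dy, dx) == (0, 0, 0):
            continue
        order = abs(dz) + abs(dy) + abs(dx)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append((dz, dy, dx))
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """BFS flood fill; returns the list of voxel-index sets, one per component."""
    offs = neighbor_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        comp = set()
        q = deque([idx])
        seen[idx] = True
        while q:
            z, y, x = q.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in offs:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    q.append((nz, ny, nx))
        comps.append(comp)
    return comps
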