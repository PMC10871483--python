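"""Independent brute-force oracles shared by the test modules."""

from collections import deque

import numpy as np


def bfs_flood_fill(values, seed, tolerance, connectivity):
    """Breadth-first flood fill within a gray band around the seed value."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if (
                    (connectivity == 6 and order == 1)
                    or (connectivity == 18 and order <= 2)
                    or connectivity == 26
                ):
                    offsets.append((dz, dy, dx))
    seed_gray = int(values[seed])
    out = np.zeros(values.shape, dtype=bool)
    out[seed] = True
    queue = deque([seed])
    shape = values.shape
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if (
                    not out[nz, ny, nx]
                    and abs(int(values[nz, ny, nx]) - seed_gray) <= tolerance
                ):
                    out[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
    return out
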