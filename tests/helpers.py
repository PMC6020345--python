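"""Independent brute-force oracles and random fixture generators.

Everything here is deliberately loop-based and naive so it cannot share a
defect with the vectorized implementations it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from nefasym import BinaryRegion

NEIGHBORS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
NEIGHBORS_8 = NEIGHBORS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def perimeter_oracle(region: BinaryRegion) -> int:
    """Count exposed unit edges one cell at a time."""
    fg = region.foreground
    total = 0
    for r, c in fg:
        for dr, dc in NEIGHBORS_4:
            if (r + dr, c + dc) not in fg:
                total += 1
    return total


def flood_fill(cells: set, start, connectivity: int = 8) -> set:
    """Cells reachable from start under the given adjacency."""
    neighbors = NEIGHBORS_8 if connectivity == 8 else NEIGHBORS_4
    seen = {start}
    queue = deque([start])
    while queue:
        r, c = queue.popleft()
        for dr, dc in neighbors:
            nxt = (r + dr, c + dc)
            if nxt in cells and nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return seen


def is_connected(region: BinaryRegion, connectivity: int = 8) -> bool:
    fg = set(region.foreground)
    if not fg:
        return False
    start = next(iter(fg))
    return flood_fill(fg, start, connectivity) == fg


def random_polyomino(rng: np.random.Generator, n_cells: int) -> BinaryRegion:
    """Grow a random 4-connected polyomino by boundary accretion."""
    cells = {(0, 0)}
    frontier = {(1, 0), (-1, 0), (0, 1), (0, -1)}
    while len(cells) < n_cells:
        pick = tuple(sorted(frontier)[rng.integers(len(frontier))])
        cells.add(pick)
        frontier.discard(pick)
        for dr, dc in NEIGHBORS_4:
            cand = (pick[0] + dr, pick[1] + dc)
            if cand not in cells:
                frontier.add(cand)
    return region_from_cells(cells)


def region_from_cells(cells, margin: int = 1) -> BinaryRegion:
    """Embed arbitrary (row, col) cells in a tight grid with a margin."""
    rows = [r for r, _ in cells]
    cols = [c for _, c in cells]
    r0, c0 = min(rows) - margin, min(cols) - margin
    shifted = [(r - r0, c - c0) for r, c in cells]
    n_rows = max(r for r, _ in shifted) + 1 + margin
    n_cols = max(c for _, c in shifted) + 1 + margin
    return BinaryRegion.from_cells(n_rows, n_cols, shifted)


def random_mask(rng: np.random.Generator, shape=(12, 12), density=0.45) -> BinaryRegion:
    """Random (possibly disconnected) mask with at least one foreground cell."""
    m = rng.random(shape) < density
    if not m.any():
        m[tuple(rng.integers(s) for s in shape)] = True
    return BinaryRegion(m)


def rotated(region: BinaryRegion, quarter_turns: int) -> BinaryRegion:
    return BinaryRegion(np.rot90(region.mask, quarter_turns))
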