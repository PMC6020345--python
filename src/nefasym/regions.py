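"""Binary region masks and raster file I/O.

The container every measure consumes is :class:`BinaryRegion`: a rectangular
cell grid with a boolean foreground.  Coordinates are 0-based ``(row, col)``
with row 0 at the top and rows increasing downward; this convention is used
throughout the package.

Masks are read from and written to standard raster formats (PNG, PGM, PBM).
Foreground is white by default; any anti-aliased or RGB input is reduced to
luminance and thresholded, so cell membership is strictly binary after
loading.  Holes are never filled on load: the measures apply to non-convex
regions, including regions with holes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "BinaryRegion",
    "EmptyRegionError",
    "load_mask",
    "save_mask",
    "largest_component",
]


class EmptyRegionError(ValueError):
    """A mask with no foreground cells was passed where a region is required."""


@dataclass(frozen=True, eq=False)
class BinaryRegion:
    """A rectangular cell grid with a boolean foreground.

    Parameters
    ----------
    mask : ndarray of bool, shape (n_rows, n_cols)
        ``True`` marks foreground cells.  The array is copied to bool and
        frozen; a region is immutable once built.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        m = m.astype(bool, copy=True)
        m.setflags(write=False)
        object.__setattr__(self, "mask", m)

    @classmethod
    def from_cells(
        cls, n_rows: int, n_cols: int, cells: Iterable[tuple[int, int]]
    ) -> "BinaryRegion":
        """Build a region from explicit (row, col) foreground coordinates."""
        m = np.zeros((n_rows, n_cols), dtype=bool)
        for r, c in cells:
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise ValueError(f"cell {(r, c)} outside {n_rows}x{n_cols} grid")
            m[r, c] = True
        return cls(m)

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @cached_property
    def area(self) -> int:
        """Number of foreground cells."""
        return int(np.count_nonzero(self.mask))

    @property
    def is_empty(self) -> bool:
        return self.area == 0

    @property
    def foreground(self) -> frozenset[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask)
        return frozenset(zip(rows.tolist(), cols.tolist()))

    def translated(self, d_row: int, d_col: int) -> "BinaryRegion":
        """Shift the foreground by an integer offset, growing the grid to fit."""
        rows, cols = np.nonzero(self.mask)
        rows = rows + d_row
        cols = cols + d_col
        if rows.size and (rows.min() < 0 or cols.min() < 0):
            raise ValueError("translation moves foreground off-grid")
        n_rows = max(self.n_rows, int(rows.max()) + 1 if rows.size else 0)
        n_cols = max(self.n_cols, int(cols.max()) + 1 if cols.size else 0)
        m = np.zeros((n_rows, n_cols), dtype=bool)
        m[rows, cols] = True
        return BinaryRegion(m)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryRegion):
            return NotImplemented
        return self.mask.shape == other.mask.shape and bool(
            np.array_equal(self.mask, other.mask)
        )

    def __repr__(self) -> str:
        return f"BinaryRegion({self.n_rows}x{self.n_cols}, area={self.area})"


def load_mask(
    path: str | Path, threshold: float = 0.5, invert: bool = False
) -> BinaryRegion:
    """Read a raster file as a binary region.

    RGB(A) images are converted to luminance first; foreground is every cell
    whose normalized intensity exceeds ``threshold`` (white-is-foreground).
    ``invert`` flips the convention for masks drawn black-on-white.

    Raises
    ------
    OSError
        If the file is missing or not a decodable raster.
    EmptyRegionError
        If thresholding leaves no foreground cell.
    """
    path = Path(path)
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.float64) / 255.0
    fg = arr > threshold
    if invert:
        fg = ~fg
    if not fg.any():
        raise EmptyRegionError(f"no foreground cells in mask: {path}")
    return BinaryRegion(fg)


def save_mask(region: BinaryRegion, path: str | Path) -> None:
    """Write a region as a raster file (format chosen by extension).

    Foreground is written white.  ``load_mask(save_mask(r))`` reproduces
    ``r`` exactly for PNG, PGM and PBM.
    """
    path = Path(path)
    arr = (region.mask.astype(np.uint8)) * 255
    img = Image.fromarray(arr, mode="L")
    if path.suffix.lower() == ".pbm":
        img = img.convert("1")
    img.save(path)


def largest_component(region: BinaryRegion, connectivity: int = 8) -> BinaryRegion:
    """Keep only the largest connected component of the foreground.

    Under the package's digital topology the default adjacency is
    8-connectivity (edge and diagonal neighbors).  Ties on area are broken by
    the component whose top-left-most cell is smallest in (row, col) order.
    Grid dimensions are preserved.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    if region.is_empty:
        raise EmptyRegionError("cannot take largest component of an empty region")
    structure = (
        np.ones((3, 3), dtype=bool)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n = ndimage.label(region.mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size)
    # np.argwhere is row-major sorted, so [0] is the lexicographic minimum cell
    best = min(candidates, key=lambda lab: tuple(np.argwhere(labels == lab)[0]))
    return BinaryRegion(labels == best)
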