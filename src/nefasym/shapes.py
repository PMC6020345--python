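"""Deterministic synthetic shape generator for the geometric experiments.

Generates the digitized squares, discs, regular polygons, chord-truncated
discs (circle-to-octagon morph) and peaked stars (star-to-dodecagon morph)
used to probe the asymmetry measure: resolution sweeps, scale stability, and
symmetry-breaking morphs.  Every generator is a pure function of its spec —
same spec, identical mask — so fixtures are reproducible without bundling
image files.

Rasterization rule: a cell belongs to the shape when its center lies inside
the ideal continuous shape (closed boundaries).  For even-sided regular
polygons and discs, membership is evaluated through absolute-value half-plane
tests that are exactly symmetric under 180-degree rotation about the center,
so a centered even-symmetric spec digitizes to an exactly 180-degree-
symmetric mask — the main end-to-end zero-asymmetry oracle.

Note on parity: exact central symmetry requires the reflection of each cell
center to land on a cell center, i.e. twice the shape center must be integer
in both coordinates and, for squares, the side must match the frame parity.
A shape centered off-lattice (e.g. a quarter cell) digitizes asymmetrically;
that digitization error is precisely what the resolution sweep measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union
from shapely import contains_xy

from .regions import BinaryRegion

__all__ = [
    "ShapeSpec",
    "rasterize",
    "disc_minus_arcs",
    "peaked_star",
    "upscale",
    "default_manifest",
]

KINDS = ("square", "disc", "regular_polygon", "peaked_star", "disc_minus_arcs")


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of a synthetic shape.

    size_px is the characteristic length in pixels: the side for squares,
    the border-to-border diameter for discs, and the vertex-to-opposite-
    vertex (peak-to-peak) distance for polygons and stars.  ``present``
    counts peaks retained (peaked_star) or octant arcs removed
    (disc_minus_arcs).  ``center`` is a continuous (row, col); default is
    the frame center ((n_rows-1)/2, (n_cols-1)/2).
    """

    kind: str
    size_px: float
    frame: tuple[int, int]
    k: int = 12
    present: int = 0
    orientation_deg: float = 0.0
    center: tuple[float, float] | None = None
    base_fraction: float = 2.0 / 3.0  # star base-polygon radius / apex radius

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.frame[0] - 1) / 2.0, (self.frame[1] - 1) / 2.0)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "size_px": self.size_px,
            "frame": list(self.frame),
            "k": self.k,
            "present": self.present,
            "orientation_deg": self.orientation_deg,
            "base_fraction": self.base_fraction,
        }
        if self.center is not None:
            d["center"] = list(self.center)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ShapeSpec":
        return cls(
            kind=d["kind"],
            size_px=d["size_px"],
            frame=tuple(d["frame"]),
            k=int(d.get("k", 12)),
            present=int(d.get("present", 0)),
            orientation_deg=float(d.get("orientation_deg", 0.0)),
            center=tuple(d["center"]) if "center" in d else None,
            base_fraction=float(d.get("base_fraction", 2.0 / 3.0)),
        )


def _grid(spec: ShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Math-convention offsets (x right, y up) of every cell center."""
    n_rows, n_cols = spec.frame
    cr, cc = spec.resolved_center()
    rr, cc_grid = np.meshgrid(
        np.arange(n_rows, dtype=np.float64),
        np.arange(n_cols, dtype=np.float64),
        indexing="ij",
    )
    return cc_grid - cc, -(rr - cr)


def _check_fits(spec: ShapeSpec, extent: float) -> None:
    n_rows, n_cols = spec.frame
    cr, cc = spec.resolved_center()
    tol = 1e-9
    if (
        cr - extent < -0.5 - tol
        or cr + extent > n_rows - 0.5 + tol
        or cc - extent < -0.5 - tol
        or cc + extent > n_cols - 0.5 + tol
    ):
        raise ValueError(
            f"{spec.kind} of size {spec.size_px} exceeds frame {spec.frame}"
        )


def _polygon_mask(
    spec: ShapeSpec, radius: float, k: int, orientation_rad: float
) -> np.ndarray:
    """Regular k-gon (circumradius ``radius``) by half-plane tests.

    Even k uses |projection| <= apothem over k/2 normal directions, which is
    exactly centrally symmetric; odd k loops all k edges.
    """
    x, y = _grid(spec)
    apothem = radius * math.cos(math.pi / k)
    inside = np.ones(x.shape, dtype=bool)
    if k % 2 == 0:
        for j in range(k // 2):
            alpha = orientation_rad + math.pi / k + 2.0 * math.pi * j / k
            proj = x * math.cos(alpha) + y * math.sin(alpha)
            inside &= np.abs(proj) <= apothem
    else:
        for j in range(k):
            alpha = orientation_rad + math.pi / k + 2.0 * math.pi * j / k
            inside &= (x * math.cos(alpha) + y * math.sin(alpha)) <= apothem
    return inside


def rasterize(spec: ShapeSpec) -> BinaryRegion:
    """Digitize a shape spec onto its frame (cell-center-inside rule)."""
    if spec.kind not in KINDS:
        raise ValueError(f"unknown shape kind: {spec.kind!r}")
    if spec.size_px < 4:
        raise ValueError(f"size_px must be >= 4, got {spec.size_px}")
    orientation = math.radians(spec.orientation_deg)

    if spec.kind == "square":
        half = spec.size_px / 2.0
        _check_fits(spec, half)
        n_rows, n_cols = spec.frame
        cr, cc = spec.resolved_center()
        r_off = np.arange(n_rows) - cr
        c_off = np.arange(n_cols) - cc
        rows_in = (r_off >= -half) & (r_off < half)
        cols_in = (c_off >= -half) & (c_off < half)
        return BinaryRegion(np.outer(rows_in, cols_in))

    if spec.kind == "disc":
        radius = spec.size_px / 2.0
        _check_fits(spec, radius)
        x, y = _grid(spec)
        return BinaryRegion(x * x + y * y <= radius * radius)

    if spec.kind == "regular_polygon":
        radius = spec.size_px / 2.0
        _check_fits(spec, radius)
        return BinaryRegion(_polygon_mask(spec, radius, spec.k, orientation))

    if spec.kind == "disc_minus_arcs":
        return disc_minus_arcs(
            spec.size_px,
            spec.present,
            spec.frame,
            center=spec.center,
            orientation_deg=spec.orientation_deg,
        )

    return peaked_star(
        spec.k,
        spec.present,
        spec.size_px,
        spec.frame,
        center=spec.center,
        orientation_deg=spec.orientation_deg,
        base_fraction=spec.base_fraction,
    )


def disc_minus_arcs(
    diameter: float,
    removed: int,
    frame: tuple[int, int],
    center: tuple[float, float] | None = None,
    orientation_deg: float = 0.0,
) -> BinaryRegion:
    """Disc with ``removed`` of its eight 45-degree arcs replaced by chords.

    Arcs are removed one octant at a time in a fixed consecutive order, so
    intermediate shapes are one-sided; removed=0 is the plain disc and
    removed=8 the inscribed regular octagon.
    """
    if not 0 <= removed <= 8:
        raise ValueError(f"removed must be in 0..8, got {removed}")
    spec = ShapeSpec("disc_minus_arcs", diameter, frame, present=removed, center=center)
    radius = diameter / 2.0
    _check_fits(spec, radius)
    x, y = _grid(spec)
    inside = x * x + y * y <= radius * radius
    chord_dist = radius * math.cos(math.pi / 8.0)
    orientation = math.radians(orientation_deg)
    for j in range(removed):
        alpha = orientation + j * math.pi / 4.0
        inside &= (x * math.cos(alpha) + y * math.sin(alpha)) <= chord_dist
    return BinaryRegion(inside)


def peaked_star(
    peaks_total: int,
    peaks_present: int,
    peak_to_peak: float,
    frame: tuple[int, int],
    center: tuple[float, float] | None = None,
    orientation_deg: float = 0.0,
    base_fraction: float = 2.0 / 3.0,
) -> BinaryRegion:
    """Regular polygon with triangular peaks on consecutive edges.

    The base is a regular ``peaks_total``-gon of circumradius
    ``base_fraction * peak_to_peak / 2``; each retained peak is a triangle
    whose base is a polygon edge and whose apex lies on the peak-to-peak
    circle at the edge-midpoint bearing.  ``peaks_present = 0`` is the plain
    polygon, ``peaks_present = peaks_total`` the full star; intermediate
    counts keep consecutive peaks, making the shape one-sided.
    """
    if not 0 <= peaks_present <= peaks_total:
        raise ValueError(
            f"peaks_present must be in 0..{peaks_total}, got {peaks_present}"
        )
    r_apex = peak_to_peak / 2.0
    r_base = base_fraction * r_apex
    spec = ShapeSpec(
        "peaked_star",
        peak_to_peak,
        frame,
        k=peaks_total,
        present=peaks_present,
        center=center,
        orientation_deg=orientation_deg,
    )
    _check_fits(spec, r_apex if peaks_present else r_base)
    orientation = math.radians(orientation_deg)

    if peaks_present == 0:
        # plain base polygon: use the exactly-symmetric half-plane path
        return BinaryRegion(
            _polygon_mask(spec, r_base, peaks_total, orientation)
        )

    k = peaks_total
    verts = [
        (
            r_base * math.cos(orientation + 2.0 * math.pi * i / k),
            r_base * math.sin(orientation + 2.0 * math.pi * i / k),
        )
        for i in range(k)
    ]
    pieces = [Polygon(verts)]
    for j in range(peaks_present):
        apex_angle = orientation + 2.0 * math.pi * (j + 0.5) / k
        apex = (r_apex * math.cos(apex_angle), r_apex * math.sin(apex_angle))
        pieces.append(Polygon([verts[j], apex, verts[(j + 1) % k]]))
    shape = unary_union(pieces)
    x, y = _grid(spec)
    inside = contains_xy(shape, x.ravel(), y.ravel()).reshape(x.shape)
    return BinaryRegion(inside)


def upscale(region: BinaryRegion, factor: int) -> BinaryRegion:
    """Nearest-neighbor upscaling: each cell becomes a factor x factor block."""
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be an integer >= 1, got {factor}")
    if factor == 1:
        return region
    return BinaryRegion(np.kron(region.mask, np.ones((factor, factor), dtype=bool)))


def default_manifest() -> dict[str, ShapeSpec]:
    """The bundled fixture suite for the geometric experiments.

    Resolution-sweep squares and discs (side/diameter 32..512), the
    circle-to-octagon morph (diameter 512 in a 563x545 frame), and the
    star-to-dodecagon morph (300 px peak-to-peak in a 331x331 frame).
    """
    manifest: dict[str, ShapeSpec] = {}
    for s in (32, 64, 128, 256, 512):
        manifest[f"sweep_square_{s:03d}"] = ShapeSpec("square", s, (s, s))
        manifest[f"sweep_disc_{s:03d}"] = ShapeSpec("disc", s, (s + 51, s + 33))
    for removed in range(9):
        manifest[f"circle_morph_c{removed + 1}"] = ShapeSpec(
            "disc_minus_arcs", 512, (563, 545), present=removed
        )
    for present in range(12, -1, -1):
        manifest[f"star_morph_s{present:02d}"] = ShapeSpec(
            "peaked_star", 300, (331, 331), k=12, present=present
        )
    manifest["dodecagon_300"] = ShapeSpec("regular_polygon", 300, (331, 331), k=12)
    return manifest
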