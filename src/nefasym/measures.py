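"""Shape measures: NEF compactness, octant asymmetry, and comparators.

The core quantity is the Normalized E-Factor (NEF), a discrete compactness
descriptor

    NEF = P / (4 * sqrt(n))

for a digital region of perimeter P (exposed unit edges) and area n (cells).
A perfect square — the most compact shape on the square grid — scores exactly
1; every other region scores more.  The asymmetry of a region is the sum of
squared NEF differences over the four vertex-opposite octant pairs of its
centroid decomposition:

    Asymmetry_NEF = sum_{i=1..4} (NEF_Ri - NEF_{Ri+4})**2

A region with 180-degree rotational symmetry about its centroid scores 0;
the score grows as opposite sectors diverge in compactness.

Also provided are the comparator formulas used when benchmarking against
other asymmetry descriptors: the reflection-based percentage score about the
centroidal principal axes (``asymmetry_ref``), the 24-component sector
feature-ratio vector (``feature_ratios``), and the clinical ABCD Total
Dermatoscopic Value (``tdv``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import Centroid, SectorDecomposition, centroid, perimeter, sector_partition
from .regions import BinaryRegion, EmptyRegionError

__all__ = [
    "NEFProfile",
    "AsymmetryResult",
    "RefAsymmetry",
    "FeatureRatios",
    "TDVInputs",
    "nef",
    "nef_profile",
    "asymmetry_nef",
    "asymmetry_nef_of_region",
    "asymmetry_ref",
    "feature_ratios",
    "tdv",
]


@dataclass(frozen=True)
class NEFProfile:
    """Per-sector NEF values for the eight octants.

    ``values[i]`` is the NEF of sector i; an empty sector contributes 0 and
    sets ``degenerate`` (the formulas stay total, callers can warn).
    """

    values: tuple[float, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != 8:
            raise ValueError(f"profile needs 8 values, got {len(self.values)}")


@dataclass(frozen=True)
class AsymmetryResult:
    """Asymmetry_NEF with its four opposite-pair terms.

    ``value`` equals the exactly-rounded sum of ``pair_terms`` (math.fsum),
    so the total is independent of pair order.
    """

    value: float
    pair_terms: tuple[float, float, float, float]
    degenerate: bool = False
    profile: NEFProfile | None = None
    decomposition: SectorDecomposition | None = field(default=None, repr=False)


@dataclass(frozen=True)
class RefAsymmetry:
    """Reflection-based asymmetry percentage about the principal axes."""

    value: float  # 100 * delta_a_min / a_total, in [0, 100]
    delta_a_min: float  # smallest one-sided area difference (cells)
    a_total: int  # area of the region in the principal frame
    axis_angle: float  # radians of the centroidal major axis
    degenerate_orientation: bool = False  # isotropic moments, angle pinned to 0


@dataclass(frozen=True)
class FeatureRatios:
    """Sector feature ratios R_i = Q_i / sum_{j != i} Q_j.

    Three descriptors (perimeter, area, classic compactness P^2/(4*pi*A))
    across eight sectors give a 24-component description vector.
    """

    perimeter: tuple[float, ...]
    area: tuple[float, ...]
    compactness: tuple[float, ...]
    degenerate: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array(self.perimeter + self.area + self.compactness)


@dataclass(frozen=True)
class TDVInputs:
    """Clinical ABCD component scores (asymmetry, border, color, dimension)."""

    a_score: float
    b_score: float
    c_score: float
    d_score: float


def nef(region: BinaryRegion) -> float:
    """Normalized E-Factor P/(4*sqrt(n)); >= 1 for every non-empty region."""
    if region.is_empty:
        raise EmptyRegionError("NEF of an empty region is undefined")
    return perimeter(region) / (4.0 * math.sqrt(region.area))


def nef_profile(decomp: SectorDecomposition) -> NEFProfile:
    """NEF of each octant; empty octants score 0 and flag the profile."""
    values = []
    degenerate = False
    for sector in decomp.sectors:
        if sector.is_empty:
            values.append(0.0)
            degenerate = True
        else:
            values.append(nef(sector))
    return NEFProfile(tuple(values), degenerate)


def asymmetry_nef(profile: NEFProfile | Sequence[float]) -> AsymmetryResult:
    """Sum of squared NEF differences over the four vertex-opposite pairs."""
    if isinstance(profile, NEFProfile):
        values = profile.values
        degenerate = profile.degenerate
        prof = profile
    else:
        values = tuple(float(v) for v in profile)
        degenerate = False
        prof = NEFProfile(values)
    if len(values) != 8:
        raise ValueError(f"need 8 NEF values, got {len(values)}")
    pair_terms = tuple((values[i] - values[i + 4]) ** 2 for i in range(4))
    return AsymmetryResult(math.fsum(pair_terms), pair_terms, degenerate, prof)


def asymmetry_nef_of_region(region: BinaryRegion) -> AsymmetryResult:
    """Full pipeline: centroid -> octant partition -> NEF profile -> score."""
    decomp = sector_partition(region)
    prof = nef_profile(decomp)
    result = asymmetry_nef(prof)
    return AsymmetryResult(
        result.value, result.pair_terms, prof.degenerate, prof, decomp
    )


# ---------------------------------------------------------------------------
# Comparator: reflection-based asymmetry about the centroidal principal axes
# ---------------------------------------------------------------------------

_ISOTROPY_EPS = 1e-9


def principal_axis_angle(region: BinaryRegion) -> tuple[float, bool]:
    """Orientation of the centroidal major axis from second-order moments.

    Returns ``(angle, degenerate)`` with angle = 0.5*atan2(2*mu11,
    mu20 - mu02) in radians (x = columns, y = rows).  When the second
    moments are isotropic (square, disc) the orientation is undefined; the
    angle is pinned to 0 and the flag set.
    """
    if region.is_empty:
        raise EmptyRegionError("orientation of an empty region is undefined")
    rows, cols = np.nonzero(region.mask)
    y = rows - rows.mean()
    x = cols - cols.mean()
    mu20 = float((x * x).sum())
    mu02 = float((y * y).sum())
    mu11 = float((x * y).sum())
    if math.hypot(2 * mu11, mu20 - mu02) < _ISOTROPY_EPS * rows.size:
        return 0.0, True
    return 0.5 * math.atan2(2 * mu11, mu20 - mu02), False


def principal_frame(region: BinaryRegion) -> tuple[BinaryRegion, float, bool]:
    """Resample the region into its principal frame (nearest neighbor).

    The mask is rotated so the centroidal major axis aligns with a grid
    axis; returns the resampled region, the original axis angle, and the
    isotropy flag.
    """
    angle, degenerate = principal_axis_angle(region)
    if angle == 0.0:
        return region, angle, degenerate
    rotated = ndimage.rotate(
        region.mask.astype(np.uint8), math.degrees(angle), reshape=True, order=0
    )
    return BinaryRegion(rotated > 0), angle, degenerate


def _reflection_difference(region: BinaryRegion, axis: int) -> float:
    """One-sided area difference under reflection across a centroidal axis.

    Reflects each foreground cell across the horizontal (axis=0) or vertical
    (axis=1) line through the centroid, rounding to the nearest cell, and
    returns half the symmetric-difference area — 0 for a perfectly
    mirror-symmetric region.
    """
    rows, cols = np.nonzero(region.mask)
    if axis == 0:
        mirrored_rows = np.rint(2.0 * rows.mean() - rows).astype(np.int64)
        mirrored = set(zip(mirrored_rows.tolist(), cols.tolist()))
    else:
        mirrored_cols = np.rint(2.0 * cols.mean() - cols).astype(np.int64)
        mirrored = set(zip(rows.tolist(), mirrored_cols.tolist()))
    fg = set(zip(rows.tolist(), cols.tolist()))
    return len(fg ^ mirrored) / 2.0


def asymmetry_ref(region: BinaryRegion) -> RefAsymmetry:
    """Reflection-based asymmetry: 100 * dA_min / A_total.

    The region is aligned with its centroidal principal axes (nearest-
    neighbor resampling), reflected across each axis in turn, and the
    smaller of the two one-sided area differences is reported as a
    percentage of the (resampled) area.
    """
    if region.is_empty:
        raise EmptyRegionError("asymmetry_ref of an empty region is undefined")
    frame_region, angle, degenerate = principal_frame(region)
    d_rows = _reflection_difference(frame_region, axis=0)
    d_cols = _reflection_difference(frame_region, axis=1)
    delta_min = min(d_rows, d_cols)
    a_total = frame_region.area
    return RefAsymmetry(
        100.0 * delta_min / a_total, delta_min, a_total, angle, degenerate
    )


# ---------------------------------------------------------------------------
# Comparator: sector feature-ratio vector and clinical TDV
# ---------------------------------------------------------------------------


def feature_ratios(decomp: SectorDecomposition) -> FeatureRatios:
    """24 sector feature ratios: R_i = Q_i / sum_{j != i} Q_j.

    Descriptors are the discrete perimeter, the area, and the classic
    compactness (thinness ratio) P^2/(4*pi*A) of each octant.  Empty octants
    contribute Q_i = 0 and set the degeneracy flag.
    """
    degenerate = any(s.is_empty for s in decomp.sectors)

    def q_values(name: str) -> tuple[float, ...]:
        qs = []
        for s in decomp.sectors:
            if s.is_empty:
                qs.append(0.0)
            elif name == "perimeter":
                qs.append(float(perimeter(s)))
            elif name == "area":
                qs.append(float(s.area))
            else:
                qs.append(perimeter(s) ** 2 / (4.0 * math.pi * s.area))
        return tuple(qs)

    ratios: dict[str, tuple[float, ...]] = {}
    for name in ("perimeter", "area", "compactness"):
        qs = q_values(name)
        total = math.fsum(qs)
        out = []
        for q in qs:
            denom = total - q
            if denom == 0.0:
                raise ValueError(f"zero denominator for {name} ratios")
            out.append(q / denom)
        ratios[name] = tuple(out)
    return FeatureRatios(
        ratios["perimeter"], ratios["area"], ratios["compactness"], degenerate
    )


def tdv(inputs: TDVInputs | None = None, /, **scores: float) -> float:
    """Total Dermatoscopic Value: 1.3*A + 0.1*B + 0.5*C + 0.5*D.

    Accepts either a :class:`TDVInputs` or the four keyword scores
    ``a_score``, ``b_score``, ``c_score``, ``d_score``.  Asymmetry carries
    the largest clinical weight.
    """
    if inputs is None:
        inputs = TDVInputs(**scores)
    elif scores:
        raise TypeError("pass either TDVInputs or keyword scores, not both")
    return (
        1.3 * inputs.a_score
        + 0.1 * inputs.b_score
        + 0.5 * inputs.c_score
        + 0.5 * inputs.d_score
    )
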