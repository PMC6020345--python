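"""NEF, octant asymmetry, and the comparator measures."""

import math

import numpy as np
import pytest

from nefasym import (
    BinaryRegion,
    Centroid,
    NEFProfile,
    SectorDecomposition,
    asymmetry_nef,
    asymmetry_nef_of_region,
    asymmetry_ref,
    feature_ratios,
    nef,
    nef_profile,
    sector_partition,
    tdv,
)
from nefasym.measures import TDVInputs, principal_frame
from nefasym.regions import EmptyRegionError
from nefasym.shapes import ShapeSpec, rasterize

from helpers import random_polyomino


class TestNEF:
    def test_square_scores_exactly_one(self):
        assert nef(BinaryRegion(np.ones((10, 10), dtype=bool))) == 1.0

    def test_single_pixel_scores_one(self):
        assert nef(BinaryRegion.from_cells(1, 1, [(0, 0)])) == 1.0

    def test_bar_1x4(self):
        region = BinaryRegion.from_cells(1, 4, [(0, c) for c in range(4)])
        assert nef(region) == pytest.approx(1.25)  # P=10, n=4

    def test_empty_rejected(self):
        with pytest.raises(EmptyRegionError):
            nef(BinaryRegion(np.zeros((2, 2), dtype=bool)))


class TestNEFProfile:
    def test_odd_disc_opposite_values_equal_exactly(self):
        region = rasterize(ShapeSpec("disc", 31, (41, 41)))
        values = nef_profile(sector_partition(region)).values
        for i in range(4):
            assert values[i] == values[i + 4]

    def test_single_pixel_profile_degenerate_zero(self):
        region = BinaryRegion.from_cells(3, 3, [(1, 1)])
        profile = nef_profile(sector_partition(region))
        assert profile.values == (0.0,) * 8
        assert profile.degenerate

    def test_identical_synthetic_sectors_equal(self):
        sector = BinaryRegion.from_cells(4, 4, [(1, 1), (1, 2)])
        decomp = SectorDecomposition((sector,) * 8, Centroid(1.5, 1.5), 16)
        values = nef_profile(decomp).values
        assert len(set(values)) == 1


class TestAsymmetryNEF:
    def test_printed_profile_worked_example(self):
        profile = (1.333, 1.420, 1.313, 1.449, 1.341, 1.470, 1.270, 1.945)
        assert asymmetry_nef(profile).value == pytest.approx(0.2499, abs=1e-3)

    def test_equal_opposite_pairs_score_zero(self):
        assert asymmetry_nef((1.2, 1.3, 1.4, 1.5, 1.2, 1.3, 1.4, 1.5)).value == 0.0

    def test_single_differing_pair(self):
        result = asymmetry_nef((2, 1, 1, 1, 1, 1, 1, 1))
        assert result.value == 1.0
        assert result.pair_terms == (1.0, 0.0, 0.0, 0.0)

    def test_value_is_sum_of_pair_terms(self, rng):
        for _ in range(20):
            values = rng.random(8) * 3
            result = asymmetry_nef(values)
            assert result.value == math.fsum(result.pair_terms)
            assert result.value >= 0.0

    def test_full_square_region_scores_zero(self):
        region = rasterize(ShapeSpec("square", 100, (100, 100)))
        assert asymmetry_nef_of_region(region).value < 1e-12

    def test_region_result_carries_profile_and_decomposition(self, rng):
        region = random_polyomino(rng, 40)
        result = asymmetry_nef_of_region(region)
        assert result.profile is not None
        assert result.decomposition is not None
        assert result.value == asymmetry_nef(result.profile).value


def _reflection_delta_oracle(region, axis):
    """Loop-based reflect-and-count on the same grid."""
    fg = set(region.foreground)
    rows = [r for r, _ in fg]
    cols = [c for _, c in fg]
    rc = sum(rows) / len(fg)
    cc = sum(cols) / len(fg)
    mirrored = set()
    for r, c in fg:
        if axis == 0:
            mirrored.add((round(2 * rc - r), c))
        else:
            mirrored.add((r, round(2 * cc - c)))
    return len(fg ^ mirrored) / 2


class TestAsymmetryRef:
    def test_axis_aligned_rectangle_scores_zero(self):
        m = np.zeros((30, 20), dtype=bool)
        m[5:25, 4:16] = True
        assert asymmetry_ref(BinaryRegion(m)).value == 0.0

    def test_half_disc_scores_zero(self):
        x, y = np.meshgrid(np.arange(41) - 20.0, np.arange(41) - 20.0, indexing="ij")
        region = BinaryRegion((x * x + y * y <= 15.5**2) & (x >= 0))
        assert asymmetry_ref(region).value == 0.0

    def test_rotated_rectangle_scores_zero(self):
        # 30-degree rotated 60x16 rectangle: principal-frame alignment undoes it
        x, y = np.meshgrid(np.arange(101) - 50.0, np.arange(101) - 50.0, indexing="ij")
        a = math.radians(30)
        u = x * math.cos(a) + y * math.sin(a)
        v = -x * math.sin(a) + y * math.cos(a)
        region = BinaryRegion((np.abs(u) <= 30) & (np.abs(v) <= 8))
        assert asymmetry_ref(region).value == 0.0

    def test_matches_reflect_and_count_oracle(self, rng):
        for n_cells in (3, 12, 40):
            region = random_polyomino(rng, n_cells)
            result = asymmetry_ref(region)
            frame_region, _, _ = principal_frame(region)
            expected = 100.0 * min(
                _reflection_delta_oracle(frame_region, 0),
                _reflection_delta_oracle(frame_region, 1),
            ) / frame_region.area
            assert result.value == pytest.approx(expected)

    def test_isotropic_region_flagged(self):
        region = BinaryRegion(np.ones((9, 9), dtype=bool))
        result = asymmetry_ref(region)
        assert result.degenerate_orientation
        assert result.axis_angle == 0.0
        assert result.value == 0.0


def _synthetic_decomp(cells_per_sector):
    sectors = tuple(
        BinaryRegion.from_cells(6, 6, cells) if cells else BinaryRegion(np.zeros((6, 6), bool))
        for cells in cells_per_sector
    )
    return SectorDecomposition(sectors, Centroid(2.5, 2.5), sum(len(c) for c in cells_per_sector))


class TestFeatureRatios:
    def test_identical_sectors_give_one_seventh(self):
        decomp = _synthetic_decomp([[(1, 1)]] * 8)
        ratios = feature_ratios(decomp)
        for vec in (ratios.perimeter, ratios.area, ratios.compactness):
            assert vec == pytest.approx((1 / 7,) * 8)

    def test_double_area_sector(self):
        cells = [[(1, 1), (1, 2)]] + [[(3, 3)]] * 7
        ratios = feature_ratios(_synthetic_decomp(cells))
        assert ratios.area[0] == pytest.approx(2 / 7)

    def test_matches_loop_oracle(self, rng):
        region = random_polyomino(rng, 60)
        decomp = sector_partition(region)
        ratios = feature_ratios(decomp)
        from nefasym import perimeter as perim

        for name, vec in (("perimeter", ratios.perimeter), ("area", ratios.area)):
            qs = []
            for s in decomp.sectors:
                if s.is_empty:
                    qs.append(0.0)
                else:
                    qs.append(float(perim(s)) if name == "perimeter" else float(s.area))
            for i in range(8):
                expected = qs[i] / sum(q for j, q in enumerate(qs) if j != i)
                assert vec[i] == pytest.approx(expected)

    def test_vector_has_24_components(self, rng):
        region = random_polyomino(rng, 50)
        assert feature_ratios(sector_partition(region)).as_vector().shape == (24,)

    def test_zero_denominator_names_descriptor(self):
        decomp = _synthetic_decomp([[(1, 1)]] + [[]] * 7)
        with pytest.raises(ValueError, match="perimeter"):
            feature_ratios(decomp)


class TestTDV:
    @pytest.mark.parametrize(
        "scores,expected",
        [((1, 1, 1, 1), 2.4), ((0, 0, 0, 0), 0.0), ((2, 0, 0, 0), 2.6)],
    )
    def test_weighted_sum(self, scores, expected):
        a, b, c, d = scores
        inputs = TDVInputs(a, b, c, d)
        assert tdv(inputs) == pytest.approx(expected)
        assert tdv(a_score=a, b_score=b, c_score=c, d_score=d) == pytest.approx(expected)
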