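"""Orientation, resampling, matching and stack interpolation of contours."""

import numpy as np
import pytest

from lheart.contour_processing import (
    ContourMatrix,
    apply_shift,
    build_matrix,
    densify_groups,
    interpolate_levels,
    match_contours,
    reorient_ccw,
    resample_contour,
    signed_area,
)
from lheart.errors import AmbiguousStackError, DegenerateContourError

Z = np.array([0.0, 0.0, 1.0])


def circle(n=24, r=1.0, z=0.0, center=(0.0, 0.0), phase=0.0):
    a = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([center[0] + r * np.cos(a),
                            center[1] + r * np.sin(a),
                            np.full(n, z)])


class TestSignedArea:
    def test_ccw_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert signed_area(sq) == pytest.approx(1.0)

    def test_reversed_square_is_negative(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])[::-1]
        assert signed_area(sq) == pytest.approx(-1.0)

    def test_matches_fan_decomposition_oracle(self, rng):
        from tests.conftest import random_simple_polygon

        poly = random_simple_polygon(rng, 15)
        fan = 0.0
        for i in range(1, len(poly) - 1):
            a, b, c = poly[0], poly[i], poly[i + 1]
            fan += 0.5 * np.cross(b - a, c - a)
        assert signed_area(poly) == pytest.approx(fan, abs=1e-12)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(DegenerateContourError):
            signed_area(np.array([[0, 0], [1, 1.0]]))

    def test_3d_contour_needs_normal(self):
        with pytest.raises(ValueError):
            signed_area(circle())


class TestReorient:
    def test_ccw_input_unchanged(self):
        c = circle()
        assert np.array_equal(reorient_ccw(c, Z), c)

    def test_cw_input_reversed_and_positive(self):
        c = circle()[::-1]
        out = reorient_ccw(c, Z)
        assert signed_area(out, Z) > 0
        assert np.array_equal(np.sort(out, axis=0), np.sort(c, axis=0))

    def test_idempotent(self):
        c = circle()[::-1]
        once = reorient_ccw(c, Z)
        assert np.array_equal(reorient_ccw(once, Z), once)

    def test_zero_area_rejected(self):
        collinear = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(DegenerateContourError):
            reorient_ccw(collinear, Z)


class TestResample:
    def test_reproduces_original_first_vertex_and_count(self):
        c = circle(12)
        out = resample_contour(c, 48)
        assert len(out) == 48
        assert np.allclose(out[0], c[0], atol=1e-9)

    def test_interpolates_knots_when_count_matches(self):
        # equal chord lengths: resampling at the original count hits the knots
        c = circle(16)
        out = resample_contour(c, 16)
        assert np.allclose(out, c, atol=1e-9)

    def test_circle_radius_preserved_within_one_percent(self):
        # 12 knots at 30° spacing: PCHIP's chordal flattening costs ~0.8%
        # radial error; denser clinical contours are far below this
        c = circle(12, r=10.0)
        out = resample_contour(c, 48)
        radii = np.linalg.norm(out[:, :2], axis=1)
        assert np.all(np.abs(radii - 10.0) / 10.0 < 0.01)
        # doubling the knot density roughly quarters the error
        out24 = resample_contour(circle(24, r=10.0), 96)
        radii24 = np.linalg.norm(out24[:, :2], axis=1)
        assert np.all(np.abs(radii24 - 10.0) / 10.0 < 0.003)

    def test_too_few_points_or_targets_rejected(self):
        with pytest.raises(DegenerateContourError):
            resample_contour(circle(3), 10)
        with pytest.raises(ValueError):
            resample_contour(circle(8), 3)


class TestMatch:
    def test_recovers_known_roll(self):
        c = circle(32)
        rolled = np.roll(c, 7, axis=0)
        k = match_contours(c, rolled)
        assert k == 7
        assert np.allclose(apply_shift(rolled, k), c, atol=1e-12)

    def test_identical_contours_give_zero(self):
        c = circle(20)
        assert match_contours(c, c) == 0

    def test_matches_exhaustive_scan_oracle(self, rng):
        a = circle(30) + rng.normal(size=(30, 3)) * 0.05
        b = np.roll(circle(30, phase=0.3), 11, axis=0) + rng.normal(size=(30, 3)) * 0.05
        k = match_contours(a, b)
        costs = [np.mean(np.linalg.norm(a - np.roll(b, -s, axis=0), axis=1))
                 for s in range(30)]
        assert k == int(np.argmin(costs))

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError):
            match_contours(circle(10), circle(12))


class TestBuildMatrix:
    def test_identical_circle_stack_gives_vertical_columns(self):
        group = [(circle(24, z=z), z) for z in (0.0, 8.0, 16.0)]
        mat = build_matrix(group, 32, Z)
        assert mat.shape == (3, 32)
        # every column is a vertical line: x/y constant across rows
        assert np.allclose(mat.points[:, :, :2] - mat.points[0:1, :, :2], 0, atol=1e-9)

    def test_rotated_circle_matched_to_minimal_twist(self):
        group = [(circle(24, z=0.0), 0.0),
                 (np.roll(circle(24, z=8.0), 9, axis=0), 8.0)]
        mat = build_matrix(group, 24, Z)
        d = np.linalg.norm(mat.points[1] - mat.points[0], axis=1)
        costs = [np.mean(np.linalg.norm(
            mat.points[0] - np.roll(mat.points[1], s, axis=0), axis=1))
            for s in range(24)]
        assert np.mean(d) <= min(costs) + 1e-9

    def test_duplicate_levels_rejected(self):
        with pytest.raises(AmbiguousStackError):
            build_matrix([(circle(), 1.0), (circle(), 1.0)], 16, Z)

    def test_dimensions_contract(self):
        group = [(circle(20, z=z), z) for z in (0, 5, 10, 15.0)]
        assert build_matrix(group, 40, Z).shape == (4, 40)


class TestInterpolateLevels:
    def make_matrix(self, radii, levels, n=24):
        rows = [circle(n, r=r, z=lv) for r, lv in zip(radii, levels)]
        return ContourMatrix(np.stack(rows), np.array(levels, float), "LV")

    def test_knot_levels_reproduced(self):
        mat = self.make_matrix([10, 12, 11], [0, 8, 16])
        out = interpolate_levels(mat, 3)
        assert np.allclose(out.points, mat.points, atol=1e-9)

    def test_two_level_column_is_linear(self):
        mat = self.make_matrix([10, 14], [0, 8])
        out = interpolate_levels(mat, 3)
        assert np.allclose(out.points[1], (mat.points[0] + mat.points[1]) / 2, atol=1e-12)

    def test_cylinder_stack_stays_on_cylinder(self):
        mat = self.make_matrix([10, 10, 10, 10], [0, 8, 16, 24])
        out = interpolate_levels(mat, 25)
        radii = np.linalg.norm(out.points[:, :, :2], axis=2)
        assert np.all(np.abs(radii - 10.0) / 10.0 < 0.005)

    def test_never_extrapolates(self):
        mat = self.make_matrix([10, 12], [0, 8])
        out = interpolate_levels(mat, 9)
        assert out.levels.min() >= 0 and out.levels.max() <= 8

    def test_fewer_levels_rejected(self):
        mat = self.make_matrix([10, 12, 11], [0, 8, 16])
        with pytest.raises(ValueError):
            interpolate_levels(mat, 2)


class TestDensifyGroups:
    def contours(self):
        out = []
        for z in (0, 8, 16, 24.0):
            out.append(("LV", circle(24, r=20, z=z)))
        for z in (40, 48.0):
            out.append(("LA", circle(24, r=12, z=z, center=(-10, 0))))
            out.append(("AO", circle(24, r=6, z=z, center=(12, 0))))
        out.append(("MERGED", circle(24, r=22, z=32)))
        return out

    def test_groups_densified_and_gap_preserved(self):
        mats, warns = densify_groups(self.contours(), Z, n=32, target_spacing_mm=2.0)
        assert set(mats) == {"LV", "LA", "AO"}
        assert not warns
        # no interpolated level falls in the bifurcation gap (24, 40)
        for m in mats.values():
            assert not np.any((m.levels > 24 + 1e-9) & (m.levels < 40 - 1e-9)) or \
                m.label == "LA" or m.label == "AO"
        assert mats["LV"].levels.max() <= 24 + 1e-9
        assert mats["LA"].levels.min() >= 40 - 1e-9

    def test_single_contour_group_passes_through_with_warning(self):
        cont = [("LV", circle(24, z=0)), ("LV", circle(24, z=8)),
                ("LA", circle(24, z=40))]
        mats, warns = densify_groups(cont, Z, n=16)
        assert "LV" in mats and "LA" not in mats
        assert any("LA" in w for w in warns)

    def test_point_count_conservation(self):
        mats, _ = densify_groups(self.contours(), Z, n=32, target_spacing_mm=2.0)
        total = sum(m.points.shape[0] * m.points.shape[1] for m in mats.values())
        assert total == sum(np.prod(m.shape) for m in mats.values())
        for m in mats.values():
            assert m.points.shape[1] == 32

    def test_cone_stack_radial_fidelity(self):
        # cone: radius shrinks linearly with height -> PCHIP should track it
        cont = [("LV", circle(48, r=30 - z, z=z)) for z in (0, 8, 16, 24.0)]
        mats, _ = densify_groups(cont, Z, n=64, target_spacing_mm=1.0)
        m = mats["LV"]
        radii = np.linalg.norm(m.points[:, :, :2], axis=2)
        expected = 30 - m.levels[:, None]
        assert np.all(np.abs(radii - expected) / expected < 0.01)

    def test_column_track_continuity(self):
        mats, _ = densify_groups(self.contours(), Z, n=32, target_spacing_mm=2.0)
        for m in mats.values():
            step = np.linalg.norm(np.diff(m.points, axis=0), axis=2)
            assert step.max() <= 3 * max(np.median(step), 1e-9)
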