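import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tiltmontage as tm
from tiltmontage.geometry import StagePoint


class TestTileGrid:
    @pytest.mark.parametrize(
        "overlap_x, overlap_y, expected_sx, expected_sy",
        [
            (1152, 576, 4608, 3516),  # printed K3 piece-coordinate spacings
            (0, 0, 5760, 4092),
        ],
    )
    def test_spacing(self, bench_frame, overlap_x, overlap_y, expected_sx, expected_sy):
        grid = tm.tile_grid(tm.MontagePattern(3, 3, overlap_x, overlap_y), bench_frame)
        assert grid.spacing_px == (expected_sx, expected_sy)
        # x neighbors differ by sx, y neighbors by sy
        assert grid.piece_coords_px[1, 0] - grid.piece_coords_px[0, 0] == expected_sx
        assert grid.piece_coords_px[3, 1] - grid.piece_coords_px[0, 1] == expected_sy

    def test_single_tile_at_origin(self, bench_frame):
        grid = tm.tile_grid(tm.MontagePattern(1, 1), bench_frame)
        assert grid.piece_coords_px.shape == (1, 3)
        assert (grid.piece_coords_px == 0).all()
        assert np.allclose(grid.image_shifts_um, 0)

    def test_image_shift_relative_to_center_tile(self, bench_frame, bench_pattern):
        grid = tm.tile_grid(bench_pattern, bench_frame)
        center = grid.tile_index(1, 1)
        assert np.allclose(grid.image_shifts_um[center], 0)
        # corner tile: one spacing away in each axis, converted to um
        expect = np.array([4608, 3516]) * 4.603e-4
        assert np.allclose(np.abs(grid.image_shifts_um[0]), expect)

    def test_overlap_too_large_rejected(self, bench_frame):
        with pytest.raises(ValueError):
            tm.tile_grid(tm.MontagePattern(2, 2, overlap_x_px=5760), bench_frame)

    @given(
        m=st.integers(1, 4),
        n=st.integers(1, 4),
        w=st.integers(8, 512),
        h=st.integers(8, 512),
        fx=st.floats(0, 0.9),
        fy=st.floats(0, 0.9),
    )
    @settings(max_examples=50, deadline=None)
    def test_spacing_formula_property(self, m, n, w, h, fx, fy):
        frame = tm.CameraFrame(w, h, 4.603)
        pat = tm.MontagePattern(m, n, int(fx * w), int(fy * h))
        grid = tm.tile_grid(pat, frame)
        assert len(grid.piece_coords_px) == m * n
        sx, sy = grid.spacing_px
        assert sx == w - pat.overlap_x_px and sy == h - pat.overlap_y_px
        assert (grid.piece_coords_px >= 0).all()
        coords = grid.piece_coords_px
        for iy in range(n):
            for ix in range(m):
                t = grid.tile_index(ix, iy)
                assert coords[t, 0] == ix * sx and coords[t, 1] == iy * sy


class TestTiltAngles:
    @pytest.mark.parametrize(
        "max_deg, expected_len", [(60, 41), (51, 35)]
    )
    def test_list_length(self, max_deg, expected_len):
        scheme = tm.TiltScheme(max_deg, 3.0, group_size=3)
        assert len(tm.generate_tilt_angles(scheme)) == expected_len

    def test_grouped_ordering_small_range(self):
        # grouped dose-symmetric ordering enumerated by hand
        scheme = tm.TiltScheme(9.0, 3.0, group_size=3)
        assert tm.generate_tilt_angles(scheme) == [0, 3, 6, 9, -3, -6, -9]

    def test_hagen_group_of_one(self):
        scheme = tm.TiltScheme(6.0, 3.0, group_size=1)
        assert tm.generate_tilt_angles(scheme) == [0, 3, -3, 6, -6]

    def test_bidirectional(self):
        scheme = tm.TiltScheme(6.0, 3.0, style="bidirectional")
        assert tm.generate_tilt_angles(scheme) == [0, 3, 6, -3, -6]

    def test_non_multiple_increment_rejected(self):
        with pytest.raises(ValueError):
            tm.TiltScheme(10.0, 3.0)

    @given(
        k=st.integers(1, 30),
        inc=st.sampled_from([1.0, 1.5, 2.0, 3.0]),
        group=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_and_side_monotonicity(self, k, inc, group):
        scheme = tm.TiltScheme(k * inc, inc, group_size=group)
        angles = tm.generate_tilt_angles(scheme)
        nominal = sorted([i * inc for i in range(-k, k + 1)])
        assert sorted(angles) == pytest.approx(nominal)
        # within each side, magnitudes never decrease
        pos = [a for a in angles if a > 0]
        neg = [a for a in angles if a < 0]
        assert pos == sorted(pos)
        assert neg == sorted(neg, reverse=True)


class TestProjectionAndCompensation:
    @pytest.mark.parametrize(
        "y, alpha, expected",
        [(1.0, 0.0, 1.0), (1.0, 60.0, 0.5), (0.0, 45.0, 0.0)],
    )
    def test_foreshortening(self, y, alpha, expected):
        x, py = tm.project_to_image(StagePoint(0.0, y), alpha)
        assert py == pytest.approx(expected)
        assert x == 0.0

    def test_zero_tilt_zero_shift(self):
        assert tm.compensation_shift(StagePoint(1.0, 2.0), 0.0) == (0.0, 0.0)

    @given(
        y=st.floats(-5, 5),
        alpha=st.floats(-80, 80),
    )
    @settings(max_examples=100, deadline=None)
    def test_compensated_residual_is_zero(self, y, alpha):
        """Projected ROI displacement relative to the compensated tile
        center vanishes to machine precision."""
        roi = StagePoint(0.0, y)
        _, projected_y = tm.project_to_image(roi, alpha)
        _, shift_y = tm.compensation_shift(roi, alpha)
        residual = projected_y - (y + shift_y)
        assert abs(residual) < 1e-9


class TestFootprint:
    def test_circle_at_zero_tilt(self, bench_beam):
        assert tm.footprint_at_tilt(bench_beam, 0.0) == (1.575, 1.575)

    def test_elongation_at_60(self, bench_beam):
        a, b = tm.footprint_at_tilt(bench_beam, 60.0)
        assert a == pytest.approx(1.575)
        assert b == pytest.approx(3.15)

    def test_area_ratio_at_45(self, bench_beam):
        a, b = tm.footprint_at_tilt(bench_beam, 45.0)
        ratio = (a * b) / (1.575**2)
        assert ratio == pytest.approx(math.sqrt(2.0))

    def test_domain_error(self, bench_beam):
        with pytest.raises(ValueError):
            tm.footprint_at_tilt(bench_beam, 90.0)


class TestUsableFov:
    def test_zero_fraction_full_frame(self, bench_frame):
        beam = tm.BeamIllumination(3.15, fringe_fraction_x=0.0)
        assert tm.usable_fov(bench_frame, beam) == (0, 5760, 0, 4092)

    def test_default_fraction_k3(self, bench_frame, bench_beam):
        # floor(0.04 * 5760) = 230 px cut from each x side
        x0, x1, y0, y1 = tm.usable_fov(bench_frame, bench_beam)
        assert (x0, x1) == (230, 5530)
        assert (y0, y1) == (0, 4092)

    def test_small_frame(self):
        frame = tm.CameraFrame(100, 80, 1.0)
        beam = tm.BeamIllumination(1.0, fringe_fraction_x=0.04)
        assert tm.usable_fov(frame, beam) == (4, 96, 0, 80)


class TestFocusTracking:
    def test_offset_beyond_edge(self, bench_frame, bench_pattern):
        grid = tm.tile_grid(bench_pattern, bench_frame)
        half_extent = 0.5 * grid.extent_px()[0] * 4.603e-4
        p = tm.focus_tracking_position(bench_pattern, bench_frame, 0.8)
        assert p.y_um == 0.0
        assert p.x_um == pytest.approx(half_extent + 1.3)
        p0 = tm.focus_tracking_position(bench_pattern, bench_frame, 0.0)
        assert p0.x_um == pytest.approx(half_extent + 0.5)

    def test_never_inside_any_illuminated_area(
        self, bench_frame, bench_beam, bench_pattern
    ):
        """At 0 deg the focus/tracking point clears every tile's beam disc
        even when the pattern is displaced by the full offset clamp."""
        grid = tm.tile_grid(bench_pattern, bench_frame)
        max_offset = 0.8
        p = tm.focus_tracking_position(bench_pattern, bench_frame, max_offset)
        r = bench_beam.radius_um
        for cx, cy in grid.image_shifts_um:
            d = math.hypot(p.x_um - (cx + max_offset), p.y_um - cy)
            assert d > r


class TestProjectedOverlapMonotonicity:
    def test_content_spacing_shrinks_with_tilt(self):
        """Image-shift spacing is fixed, but the projected content of
        y-adjacent tiles converges as y*cos(alpha): overlap grows with
        |alpha|."""
        sy_um = 3516 * 4.603e-4
        overlaps = []
        for alpha in [0, 15, 30, 45, 60]:
            _, content_dy = tm.project_to_image(StagePoint(0.0, sy_um), alpha)
            overlaps.append(sy_um - content_dy)  # extra projected overlap
        assert all(b > a for a, b in zip(overlaps, overlaps[1:]))
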