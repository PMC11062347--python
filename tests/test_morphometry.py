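import numpy as np
import pytest

from echomorph import (
    MuscleMask,
    PhantomSpec,
    RoiPolygon,
    UltrasoundFrame,
    area_cm2,
    average_replicates,
    centroid,
    classic_axes,
    gray_stats,
    measure,
    overflow_flag,
    principal_axes,
    rasterize,
    render_phantom,
)
from echomorph.errors import DegenerateAxesError, DegenerateRoiError

from conftest import brute_force_mask, largest_four_connected


def _mask_from(points, shape=(20, 20)):
    m = np.zeros(shape, dtype=bool)
    for c, r in points:
        m[r, c] = True
    return MuscleMask(m)


class TestRasterize:
    def test_square_on_pixel_centers_inclusive(self, flat_frame):
        roi = RoiPolygon([(10, 10), (19, 10), (19, 19), (10, 19)])
        mask = rasterize(roi, flat_frame)
        assert mask.n_pixels == 100  # 10x10, boundary-inclusive

    def test_triangle_matches_brute_force(self, flat_frame, triangle_roi):
        mask = rasterize(triangle_roi, flat_frame)
        assert mask.n_pixels == 15
        oracle = brute_force_mask(triangle_roi.vertices, 6, 6)
        np.testing.assert_array_equal(mask.labelled[:6, :6], oracle)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_polygons_match_brute_force(self, seed):
        """Rasterized mask is identical to the independent point-in-polygon
        oracle for random convex polygons with fractional vertices."""
        rng = np.random.default_rng(seed)
        frame = UltrasoundFrame(np.zeros((24, 24), dtype=np.uint8), 8, 0.05, 0.05)
        ang = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(3, 8)))
        rad = rng.uniform(3, 9)
        verts = np.column_stack([11 + rad * np.cos(ang), 11 + rad * np.sin(ang)])
        roi = RoiPolygon(verts)
        mask = rasterize(roi, frame)
        oracle = largest_four_connected(brute_force_mask(verts, 24, 24))
        np.testing.assert_array_equal(mask.labelled, oracle)

    def test_polygon_outside_frame_is_degenerate(self, flat_frame):
        roi = RoiPolygon([(200, 200), (210, 200), (205, 210)])
        with pytest.raises(DegenerateRoiError):
            rasterize(roi, flat_frame)

    def test_sub_pixel_sliver_is_degenerate(self, flat_frame):
        roi = RoiPolygon([(10.2, 10.2), (10.8, 10.2), (10.5, 10.8)])
        with pytest.raises(DegenerateRoiError):
            rasterize(roi, flat_frame)


class TestAreaCentroid:
    def test_area_is_count_times_pixel_area(self):
        frame = UltrasoundFrame(np.zeros((50, 50), dtype=np.uint8), 8, 0.05, 0.05)
        m = np.zeros((50, 50), dtype=bool)
        m[10:20, 10:20] = True
        assert area_cm2(MuscleMask(m), frame) == pytest.approx(0.25)

    def test_single_pixel_centroid(self):
        frame = UltrasoundFrame(np.zeros((30, 30), dtype=np.uint8), 8, 0.01, 0.01)
        mask = _mask_from([(10, 20)], shape=(30, 30))
        assert centroid(mask, frame) == pytest.approx((0.10, 0.20))

    def test_l_shape_centroid(self, unit_frame):
        mask = _mask_from([(0, 0), (1, 0), (0, 1)])
        assert centroid(mask, unit_frame) == pytest.approx((1 / 3, 1 / 3))

    def test_scaling_doubles_extents_quadruples_area(self):
        """Doubling both spacings scales area by exactly 4 and every linear
        extent by exactly 2."""
        rng = np.random.default_rng(3)
        m = np.zeros((40, 40), dtype=bool)
        m[5:30, 8:25] = True
        m[12, 30:35] = True
        mask = MuscleMask(m)
        f1 = UltrasoundFrame(np.zeros((40, 40), dtype=np.uint8), 8, 0.01, 0.02)
        f2 = UltrasoundFrame(np.zeros((40, 40), dtype=np.uint8), 8, 0.02, 0.04)
        assert area_cm2(mask, f2) == pytest.approx(4 * area_cm2(mask, f1), rel=1e-12)
        x1, y1 = classic_axes(mask, f1)
        x2, y2 = classic_axes(mask, f2)
        assert (x2, y2) == pytest.approx((2 * x1, 2 * y1), rel=1e-12)
        *_, e1a, e1b = principal_axes(mask, f1)
        *_, e2a, e2b = principal_axes(mask, f2)
        assert (e2a, e2b) == pytest.approx((2 * e1a, 2 * e1b), rel=1e-12)


@pytest.fixture(scope="module")
def ellipse():
    frame, roi, _ = render_phantom(PhantomSpec(speckle_cv=0.0))
    return rasterize(roi, frame), frame


class TestPrincipalAxes:

    def test_ellipse_eigvals_match_second_moments(self, ellipse):
        """Uniform ellipse: positional variances are a²/4 and b²/4."""
        mask, frame = ellipse
        _, vals, x_eig, y_eig = principal_axes(mask, frame)
        assert vals[0] == pytest.approx(1.5**2 / 4, rel=0.02)
        assert vals[1] == pytest.approx(0.75**2 / 4, rel=0.02)
        assert x_eig == pytest.approx(3.0, rel=0.02)
        assert y_eig == pytest.approx(1.5, rel=0.02)
        assert x_eig >= y_eig

    @pytest.mark.parametrize("theta", [10, 30, 45, 60, 80])
    def test_rotation_invariance_of_eigen_extents(self, theta):
        frame, roi, _ = render_phantom(PhantomSpec(theta_deg=theta, speckle_cv=0.0))
        mask = rasterize(roi, frame)
        vecs, _, x_eig, y_eig = principal_axes(mask, frame)
        assert x_eig == pytest.approx(3.0, rel=0.02)
        assert y_eig == pytest.approx(1.5, rel=0.02)
        # recovered major axis direction matches the generating rotation
        ang = np.degrees(np.arctan2(vecs[0, 1], vecs[0, 0])) % 180
        assert min(abs(ang - theta), abs(ang - theta - 180)) < 1.0

    def test_circle_tie_break_prefers_image_x(self):
        frame, roi, _ = render_phantom(
            PhantomSpec(a_cm=1.0, b_cm=1.0, speckle_cv=0.0)
        )
        mask = rasterize(roi, frame)
        vecs, vals, _, _ = principal_axes(mask, frame)
        assert vals[1] == pytest.approx(vals[0], rel=0.02)
        assert abs(vecs[0] @ [1, 0]) > abs(vecs[0] @ [0, 1]) or np.allclose(
            abs(vecs[0]), [1, 0]
        )

    def test_eigvecs_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(8)
        m = np.zeros((30, 30), dtype=bool)
        m[rng.integers(0, 30, 60), rng.integers(0, 30, 60)] = True
        frame = UltrasoundFrame(np.zeros((30, 30), dtype=np.uint8), 8, 0.01, 0.013)
        vecs, vals, *_ = principal_axes(MuscleMask(m), frame)
        np.testing.assert_allclose(vecs @ vecs.T, np.eye(2), atol=1e-9)
        assert vals[0] >= vals[1] >= 0
        assert vecs[0, 0] >= 0 and vecs[1, 0] >= 0

    def test_single_pixel_is_degenerate(self, unit_frame):
        with pytest.raises(DegenerateAxesError):
            principal_axes(_mask_from([(3, 3)]), unit_frame)

    def test_collinear_mask_second_eigenvalue_zero(self, unit_frame):
        mask = _mask_from([(2, 5), (3, 5), (4, 5), (5, 5)])
        _, vals, x_eig, y_eig = principal_axes(mask, unit_frame)
        assert vals[1] == pytest.approx(0.0, abs=1e-12)
        assert y_eig == pytest.approx(0.0, abs=1e-12)


class TestClassicAxes:
    def test_axis_aligned_ellipse(self):
        frame, roi, _ = render_phantom(PhantomSpec(speckle_cv=0.0))
        mask = rasterize(roi, frame)
        x, y = classic_axes(mask, frame)
        assert x == pytest.approx(3.0, rel=0.02)
        assert y == pytest.approx(1.5, rel=0.02)

    def test_rotated_ellipse_matches_bounding_box_closed_form(self):
        frame, roi, truth = render_phantom(PhantomSpec(theta_deg=30, speckle_cv=0.0))
        mask = rasterize(roi, frame)
        x, y = classic_axes(mask, frame)
        assert x == pytest.approx(2.704, rel=0.02)
        assert y == pytest.approx(1.984, rel=0.02)
        assert (x, y) == pytest.approx((truth["x_cm"], truth["y_cm"]), rel=0.02)

    def test_single_row(self):
        frame = UltrasoundFrame(np.zeros((20, 20), dtype=np.uint8), 8, 0.1, 0.1)
        mask = _mask_from([(c, 5) for c in range(3, 14)])
        assert classic_axes(mask, frame) == pytest.approx((1.0, 0.0))

    def test_invariant_to_vertex_order(self, flat_frame):
        verts = [(10, 10), (40, 12), (45, 35), (12, 30)]
        m1 = rasterize(RoiPolygon(verts), flat_frame)
        m2 = rasterize(RoiPolygon(verts[::-1]), flat_frame)
        assert classic_axes(m1, flat_frame) == classic_axes(m2, flat_frame)


class TestGrayStats:
    def test_constant_8bit(self, flat_frame):
        m = np.zeros((100, 100), dtype=bool)
        m[40:60, 40:60] = True
        assert gray_stats(flat_frame, MuscleMask(m)) == pytest.approx((128.0, 0.0))

    def test_16bit_full_scale_maps_to_255(self):
        frame = UltrasoundFrame(np.full((32, 32), 65535, dtype=np.uint16), 16, 0.01, 0.01)
        m = np.zeros((32, 32), dtype=bool)
        m[10:20, 10:20] = True
        assert gray_stats(frame, MuscleMask(m)) == pytest.approx((255.0, 0.0))

    def test_two_pixel_mean_and_population_sd(self):
        px = np.zeros((32, 32), dtype=np.uint8)
        px[5, 6] = 255
        frame = UltrasoundFrame(px, 8, 0.01, 0.01)
        mask = _mask_from([(5, 5), (6, 5)], shape=(32, 32))
        assert gray_stats(frame, mask) == pytest.approx((127.5, 127.5))


class TestOverflow:
    def test_interior_mask_no_overflow(self, flat_frame):
        m = np.zeros((100, 100), dtype=bool)
        m[40:60, 40:60] = True
        assert overflow_flag(MuscleMask(m), flat_frame) is False

    def test_lateral_contact_triggers(self, flat_frame):
        m = np.zeros((100, 100), dtype=bool)
        m[40:60, 1:30] = True  # min col = 1, within margin 2
        assert overflow_flag(MuscleMask(m), flat_frame) is True

    def test_depth_contact_does_not_trigger(self, flat_frame):
        m = np.zeros((100, 100), dtype=bool)
        m[95:100, 40:60] = True  # touches bottom row only
        assert overflow_flag(MuscleMask(m), flat_frame) is False


class TestMeasureAndReplicates:
    def test_phantom_end_to_end(self):
        frame, roi, truth = render_phantom(
            PhantomSpec(theta_deg=20, muscle_gray=90, speckle_cv=0.3, seed=11)
        )
        rec = measure(frame, roi)
        assert rec.area_cm2 == pytest.approx(truth["area_cm2"], rel=0.01)
        assert rec.x_eigen_cm == pytest.approx(3.0, rel=0.02)
        assert rec.y_eigen_cm == pytest.approx(1.5, rel=0.02)
        assert abs(rec.gray_mean - 90) < 3
        assert rec.overflow is False

    def test_clipped_phantom_flags_overflow(self):
        frame, roi, truth = render_phantom(PhantomSpec(center_cm=(0.2, 2.0), seed=1))
        rec = measure(frame, roi)
        assert truth["overflow"] and rec.overflow

    def test_sub_fat_distance(self):
        frame, roi, _ = render_phantom(PhantomSpec(speckle_cv=0.0))
        rec = measure(frame, roi, sub_fat_points=[(10, 10), (10, 60)])
        assert rec.sub_fat_cm == pytest.approx(0.50)

    def test_average_replicates_means_and_or(self):
        frame1, roi1, _ = render_phantom(PhantomSpec(seed=1))
        frame2, roi2, _ = render_phantom(PhantomSpec(center_cm=(0.4, 2.0), seed=2))
        r1, r2 = measure(frame1, roi1), measure(frame2, roi2)
        avg = average_replicates([r1, r2])
        assert avg.area_cm2 == pytest.approx((r1.area_cm2 + r2.area_cm2) / 2)
        assert avg.gray_mean == pytest.approx((r1.gray_mean + r2.gray_mean) / 2)
        assert avg.overflow is True  # one truncated replicate taints the pair
        assert average_replicates([r1]) is r1
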