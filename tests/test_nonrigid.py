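"""Boundary extraction, displacement estimation and dense warping."""

import numpy as np
import pytest

from histo25d.bspline import BSplineField2D, random_smooth_field
from histo25d.nonrigid import (
    DisplacementField,
    build_registration_mask,
    estimate_displacement,
    extract_boundary,
    push_points_through_field,
    warp_dense,
)


def _disk(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


class TestExtractBoundary:
    def test_disk_perimeter_close_to_circumference(self):
        b = extract_boundary(_disk((128, 128), (64, 64), 50))
        assert b.perimeter_px() == pytest.approx(2 * np.pi * 50, rel=0.05)
        # the raw pixel count of a thin contour is ~4*sqrt(2)*r instead
        assert b.boundary.sum() == pytest.approx(4 * np.sqrt(2) * 50, rel=0.05)

    def test_sdt_at_disk_center(self):
        b = extract_boundary(_disk((128, 128), (64, 64), 50))
        assert b.sdt[64, 64] == pytest.approx(-50, abs=1.0)

    def test_sdt_zero_on_boundary(self):
        b = extract_boundary(_disk((64, 64), (32, 32), 20))
        assert np.abs(b.sdt[b.boundary]).max() <= 0.5

    def test_boundary_extraction_idempotent(self):
        m = _disk((64, 64), (32, 32), 20)
        b1 = extract_boundary(m)
        b2 = extract_boundary(b1.mask)
        np.testing.assert_array_equal(b1.boundary, b2.boundary)

    def test_hole_rims_kept_by_default(self):
        m = _disk((128, 128), (64, 64), 50) & ~_disk((128, 128), (64, 64), 15)
        b = extract_boundary(m)
        assert b.sdt[64, 64] > 0          # hole interior is outside
        filled = extract_boundary(m, fill_holes=True)
        assert filled.sdt[64, 64] < 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_boundary(np.zeros((10, 10), dtype=bool))


class TestRegistrationMask:
    def test_single_section_bbox(self):
        m = np.zeros((40, 60), dtype=bool)
        m[10:20, 15:35] = True
        union, bbox = build_registration_mask([m])
        assert bbox == (15, 10, 35, 20)
        np.testing.assert_array_equal(union, m)

    def test_two_offset_rectangles_hull(self):
        a = np.zeros((50, 50), dtype=bool)
        b = np.zeros((50, 50), dtype=bool)
        a[5:15, 5:15] = True
        b[30:45, 20:40] = True
        _, bbox = build_registration_mask([a, b])
        assert bbox == (5, 5, 40, 45)

    def test_union_area_matches_pixelwise_or(self, rng):
        masks = [rng.random((30, 30)) > 0.6 for _ in range(4)]
        union, _ = build_registration_mask(masks)
        expected = masks[0] | masks[1] | masks[2] | masks[3]
        np.testing.assert_array_equal(union, expected)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            build_registration_mask([np.zeros((5, 5), dtype=bool)])


class TestWarpDense:
    def test_zero_field_is_identity(self, rng):
        img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
        out = warp_dense(img, DisplacementField.zero((32, 32)))
        np.testing.assert_array_equal(out, img)

    def test_constant_field_shifts_backward(self):
        # backward convention: u=+5 samples 5 px to the right, so content
        # moves LEFT: output(x) = input(x + 5)
        img = np.zeros((20, 20))
        img[10, 12] = 255.0
        fld = DisplacementField(np.full((20, 20), 5.0), np.zeros((20, 20)), 8)
        out = warp_dense(img, fld)
        assert out[10, 7] == 255.0

    def test_out_of_bounds_white(self):
        img = np.full((10, 10), 40.0)
        fld = DisplacementField(np.full((10, 10), 100.0), np.zeros((10, 10)), 8)
        assert np.all(warp_dense(img, fld) == 255.0)

    def test_push_points_inverts_the_resampling(self, rng):
        u, v = random_smooth_field((64, 64), 16, 4.0, rng)
        fld = DisplacementField(u, v, 16)
        pts = rng.random((10, 2)) * 40 + 12
        q = push_points_through_field(fld, pts)
        # q + d(q) must return to the source point
        from histo25d.nonrigid import sample_field_at_points
        np.testing.assert_allclose(q + sample_field_at_points(fld, q), pts,
                                   atol=1e-3)


class TestEstimateDisplacement:
    def test_already_aligned_gives_tiny_field(self):
        b = extract_boundary(_disk((96, 96), (48, 48), 30))
        fld = estimate_displacement(b, b, n_iterations=40)
        assert np.percentile(fld.magnitude(), 99) < 0.5

    def test_zero_iterations_gives_zero_field(self):
        b = extract_boundary(_disk((64, 64), (32, 32), 20))
        fld = estimate_displacement(b, b, n_iterations=0)
        assert fld.magnitude().max() == 0.0

    def test_known_warp_halves_boundary_distance(self, rng):
        shape = (128, 128)
        mask = _disk(shape, (64, 64), 42) & ~_disk(shape, (50, 60), 10)
        u, v = random_smooth_field(shape, 48, 6.0, rng)
        true = DisplacementField(u, v, 48)
        warped = warp_dense(mask, true, is_mask=True)
        fixed = extract_boundary(mask)
        moving = extract_boundary(warped)
        pre = np.abs(fixed.sdt[moving.boundary]).mean()
        fld = estimate_displacement(fixed, moving, n_iterations=90)
        realigned = extract_boundary(warp_dense(warped, fld, is_mask=True))
        post = np.abs(fixed.sdt[realigned.boundary]).mean()
        assert post <= 0.5 * pre

    def test_objective_trace_non_increasing(self):
        mask = _disk((96, 96), (48, 48), 30)
        rng = np.random.default_rng(5)
        u, v = random_smooth_field((96, 96), 48, 5.0, rng)
        warped = warp_dense(mask, DisplacementField(u, v, 48), is_mask=True)
        fld = estimate_displacement(extract_boundary(mask),
                                    extract_boundary(warped), n_iterations=60)
        trace = np.asarray(fld.objective_trace)
        assert len(trace) > 3
        assert np.all(np.diff(trace) <= 1e-10)

    def test_mask_overlap_strictly_improves(self, rng):
        shape = (96, 96)
        mask = _disk(shape, (48, 48), 30)
        u, v = random_smooth_field(shape, 48, 6.0, rng)
        warped = warp_dense(mask, DisplacementField(u, v, 48), is_mask=True)
        fld = estimate_displacement(extract_boundary(mask),
                                    extract_boundary(warped), n_iterations=60)
        realigned = warp_dense(warped, fld, is_mask=True)
        before = (warped & mask).sum() / (warped | mask).sum()
        after = (realigned & mask).sum() / (realigned | mask).sum()
        assert after > before

    def test_shape_mismatch_rejected(self):
        a = extract_boundary(_disk((64, 64), (32, 32), 20))
        b = extract_boundary(_disk((96, 96), (48, 48), 20))
        with pytest.raises(ValueError):
            estimate_displacement(a, b)


class TestBSplineBasis:
    def test_partition_of_unity(self):
        from histo25d.bspline import basis_matrix
        B = basis_matrix(100, 16)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_adjoint_consistency(self, rng):
        """project_gradient is the exact adjoint of dense evaluation."""
        field = BSplineField2D((40, 48), 12)
        c = rng.normal(size=field.n_params)
        gu = rng.normal(size=(40, 48))
        gv = rng.normal(size=(40, 48))
        u, v = field.dense(c)
        lhs = np.sum(u * gu) + np.sum(v * gv)
        rhs = np.dot(field.project_gradient(gu, gv), c)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_random_field_peak_amplitude(self, rng):
        u, v = random_smooth_field((64, 64), 16, 6.0, rng)
        assert np.sqrt(u**2 + v**2).max() == pytest.approx(6.0, abs=1e-9)
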