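import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from skimage import draw

from chemoguide import (
    CellObject,
    CellShapeSpec,
    ImageFrame,
    aspect_ratio,
    circularity,
    classify_protrusive,
    ellipse_circularity,
    generate_cell_shapes,
    morphology_summary,
    segment_cells,
)
from chemoguide.morphology import circularity_from_measurements, is_protrusive


def disc_mask(r=30, pad=5):
    m = np.zeros((2 * (r + pad) + 1,) * 2, dtype=bool)
    rr, cc = draw.disk((r + pad, r + pad), r + 0.5)
    m[rr, cc] = True
    return m


def ellipse_mask(a, b, pad=5):
    m = np.zeros((2 * (int(b) + pad) + 1, 2 * (int(a) + pad) + 1), dtype=bool)
    rr, cc = draw.ellipse(int(b) + pad, int(a) + pad, b, a)
    m[rr, cc] = True
    return m


def make_cell(circ, ar):
    return CellObject(
        mask=np.ones((3, 3), bool), bbox_origin_px=(0, 0), centroid_um=(0, 0),
        area_um2=9.0, perimeter_um=12.0, aspect_ratio=ar, circularity=circ,
        solidity=1.0, frame_time_h=0.0,
    )


class TestCircularity:
    def test_analytic_disc_is_one(self):
        r = 17.3
        assert circularity_from_measurements(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_analytic_square(self):
        s = 42.0
        assert circularity_from_measurements(s**2, 4 * s) == pytest.approx(np.pi / 4)

    def test_rasterized_ellipse_matches_elliptic_integral(self):
        """Traced-contour circularity agrees with the exact-perimeter value
        (Ramanujan II formula) within 2% for a 4:1 ellipse, 120 px major axis."""
        a, b = 60.0, 15.0
        mask = ellipse_mask(a, b)
        h = ((a - b) / (a + b)) ** 2
        p_ram = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        expected = 4 * np.pi * (np.pi * a * b) / p_ram**2
        assert circularity(mask) == pytest.approx(expected, rel=0.02)

    def test_rasterized_disc_near_one(self):
        assert circularity(disc_mask(40)) == pytest.approx(1.0, abs=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            circularity(np.zeros((5, 5), dtype=bool))

    def test_translation_and_rot90_invariance(self):
        m = ellipse_mask(25, 10)
        base = circularity(m)
        assert circularity(np.rot90(m)) == pytest.approx(base, abs=1e-12)
        assert circularity(np.pad(m, ((7, 0), (0, 13)))) == pytest.approx(base, abs=1e-12)


class TestAspectRatio:
    def test_disc_is_exactly_one(self):
        assert aspect_ratio(disc_mask(20)) == 1.0

    def test_square_is_exactly_one(self):
        assert aspect_ratio(np.ones((30, 30), dtype=bool)) == 1.0

    def test_rasterized_ellipse_4(self):
        assert aspect_ratio(ellipse_mask(50, 12.5)) == pytest.approx(4.0, abs=0.05)

    def test_rectangle_matches_side_ratio(self):
        """Closed-form second moments of a rectangle give axis ratio = side ratio."""
        m = np.zeros((40, 100), dtype=bool)
        m[5:35, 5:95] = True  # 30 x 90
        assert aspect_ratio(m) == pytest.approx(3.0, abs=0.05)

    def test_rot90_and_translation_invariance(self):
        m = ellipse_mask(30, 10)
        base = aspect_ratio(m)
        assert aspect_ratio(np.rot90(m)) == pytest.approx(base, abs=1e-9)
        assert aspect_ratio(np.pad(m, ((3, 0), (0, 9)))) == pytest.approx(base, abs=1e-9)

    def test_scaling_drift_small(self):
        small = ellipse_mask(25, 10)
        big = ellipse_mask(75, 30)
        assert aspect_ratio(big) == pytest.approx(aspect_ratio(small), rel=0.02)

    def test_degenerate_line_large_finite(self):
        m = np.zeros((3, 60), dtype=bool)
        m[1, :] = True
        ar = aspect_ratio(m)
        assert np.isfinite(ar) and ar > 100

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            aspect_ratio(np.eye(2, dtype=bool))


class TestEllipseCircularity:
    def test_circle_limit_exact(self):
        assert ellipse_circularity(1.0) == 1.0

    def test_matches_quadrature_oracle(self):
        """Independent high-order quadrature of the perimeter integral."""
        for ar in (1.5, 3.0, 6.0):
            a, b = ar, 1.0
            integrand = lambda t: np.sqrt(a**2 * np.sin(t) ** 2 + b**2 * np.cos(t) ** 2)
            p, _ = quad(integrand, 0, 2 * np.pi, limit=200, epsabs=1e-12)
            expected = 4 * np.pi * (np.pi * a * b) / p**2
            assert ellipse_circularity(ar) == pytest.approx(expected, abs=1e-8)

    def test_strictly_decreasing(self):
        assert ellipse_circularity(6.0) < ellipse_circularity(3.0) < 1.0
        ars = np.linspace(1, 10, 50)
        assert np.all(np.diff(ellipse_circularity(ars)) < 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ellipse_circularity(0.5)


class TestClassifyProtrusive:
    def test_perfect_ellipse_not_protrusive(self):
        mask = ellipse_mask(45, 15)
        cell = make_cell(circularity(mask), aspect_ratio(mask))
        assert classify_protrusive(cell) is False

    def test_star_is_protrusive(self):
        """A 6-armed star falls far below the same-AR ellipse reference."""
        from chemoguide.synthetic import _boundary_mask

        mask = _boundary_mask(1.0, 3000.0, protrusion_count=6, protrusion_depth=0.45)
        circ, ar = circularity(mask), aspect_ratio(mask)
        assert circ < 0.8 * ellipse_circularity(ar)
        assert classify_protrusive(make_cell(circ, ar)) is True

    def test_boundary_equality_is_false(self):
        ref = float(ellipse_circularity(2.0))
        assert classify_protrusive(make_cell(0.8 * ref, 2.0)) is False
        assert classify_protrusive(make_cell(0.8 * ref - 1e-9, 2.0)) is True

    @given(st.floats(0.05, 1.0), st.floats(1.0, 8.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_circularity(self, circ, ar):
        """Lowering circularity at fixed AR never flips protrusive -> not."""
        if is_protrusive(circ, ar):
            assert is_protrusive(circ * 0.5, ar)


class TestSegmentation:
    def test_blank_frame_empty_list(self):
        cells = segment_cells(ImageFrame(np.zeros((64, 64)), 1.0, "cells"))
        assert cells == []

    def test_single_ellipse_detected(self):
        img = np.zeros((128, 128))
        rr, cc = draw.ellipse(64, 64, 11, 23)  # ~800 px^2 at 1 um/px
        img[rr, cc] = 100.0
        cells = segment_cells(ImageFrame(img, 1.0, "cells"), min_area_um2=100,
                              max_area_um2=10000)
        assert len(cells) == 1
        assert cells[0].aspect_ratio == pytest.approx(23 / 11, rel=0.05)
        assert cells[0].centroid_um[0] == pytest.approx(64, abs=1.0)

    def test_border_touching_discarded(self):
        img = np.zeros((64, 64))
        img[0:10, 20:40] = 50.0  # touches top border
        img[30:44, 20:40] = 50.0  # interior
        cells = segment_cells(ImageFrame(img, 1.0, "cells"), min_area_um2=50)
        assert len(cells) == 1
        assert cells[0].centroid_um[1] == pytest.approx(36.5, abs=1.0)

    def test_generator_placed_cells_recovered(self, rng):
        """Non-overlapping generated cells are all found with centroid
        error below one pixel."""
        psz = 1.0
        shapes = generate_cell_shapes(
            CellShapeSpec(n_cells=20, ar_log_bounds=(1.0, 3.0), area_um2=600.0, seed=8),
            psz,
        )
        img = np.zeros((640, 640))
        centers = []
        k = 0
        for m, _ in shapes:  # 5x4 grid, guaranteed non-overlapping
            r0, c0 = 64 + 128 * (k // 5), 64 + 128 * (k % 5)
            h, w = m.shape
            img[r0 : r0 + h, c0 : c0 + w] += 80.0 * m
            ys, xs = np.nonzero(m)
            centers.append((c0 + xs.mean(), r0 + ys.mean()))
            k += 1
        cells = segment_cells(ImageFrame(img, psz, "cells"), min_area_um2=100,
                              max_area_um2=10000)
        assert len(cells) == 20
        got = np.array([c.centroid_um for c in cells])
        for cx, cy in centers:
            d = np.hypot(got[:, 0] - cx, got[:, 1] - cy).min()
            assert d <= 1.0

    def test_solidity_filter(self):
        img = np.zeros((128, 128))
        rr, cc = draw.disk((64, 64), 18)
        img[rr, cc] = 100.0
        assert len(segment_cells(ImageFrame(img, 1.0, "cells"), min_solidity=0.95)) == 1
        # a thin cross has low solidity
        img2 = np.zeros((128, 128))
        img2[60:68, 20:108] = 100.0
        img2[20:108, 60:68] = 100.0
        assert segment_cells(ImageFrame(img2, 1.0, "cells"), min_solidity=0.8,
                             max_area_um2=50000) == []


class TestMorphologySummary:
    def test_discs_all_round(self):
        cells = [make_cell(1.0, 1.0) for _ in range(10)]
        s = morphology_summary(cells)
        assert s.frac_ar_gt3 == 0.0 and s.frac_protrusive == 0.0

    def test_counting_fractions(self):
        cells = [make_cell(0.9, ar) for ar in (2, 4, 7, 8)]
        s = morphology_summary(cells)
        assert s.frac_ar_gt3 == 0.75
        assert s.frac_ar_gt6 == 0.5
        assert s.frac_ar_gt6 <= s.frac_ar_gt3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            morphology_summary([])

    def test_protrusive_fraction_recovered_from_generator(self):
        """A cohort generated with 30% protrusive ground truth is recovered
        within the binomial 95% interval."""
        shapes = generate_cell_shapes(
            CellShapeSpec(n_cells=200, protrusive_fraction=0.3, seed=13), 1.0
        )
        cells = [
            make_cell(circularity(m), aspect_ratio(m)) for m, _ in shapes
        ]
        s = morphology_summary(cells)
        margin = 1.96 * np.sqrt(0.3 * 0.7 / 200)
        assert abs(s.frac_protrusive - 0.3) <= margin


class TestGeneratorClassifierLoop:
    @pytest.mark.parametrize("frac,expected", [(0.0, False), (1.0, True)])
    def test_closed_loop(self, frac, expected):
        shapes = generate_cell_shapes(
            CellShapeSpec(n_cells=25, protrusive_fraction=frac, seed=3), 1.0
        )
        for m, truth in shapes:
            assert truth["protrusive"] is expected
            assert is_protrusive(circularity(m), aspect_ratio(m)) is expected

    def test_discs_high_circularity(self):
        shapes = generate_cell_shapes(
            CellShapeSpec(n_cells=10, ar_log_bounds=(1.0, 1.0),
                          protrusive_fraction=0.0, seed=1), 1.0
        )
        for m, _ in shapes:
            assert circularity(m) >= 0.98

    def test_ar_recovery_within_5pct(self):
        shapes = generate_cell_shapes(
            CellShapeSpec(n_cells=30, ar_log_bounds=(1.0, 8.0),
                          area_um2=800.0, protrusive_fraction=0.0, seed=9), 1.0
        )
        for m, truth in shapes:
            assert m.sum() >= 300
            assert aspect_ratio(m) == pytest.approx(truth["ar"], rel=0.05)

    def test_determinism(self):
        a = generate_cell_shapes(CellShapeSpec(n_cells=5, protrusive_fraction=0.5, seed=7), 1.0)
        b = generate_cell_shapes(CellShapeSpec(n_cells=5, protrusive_fraction=0.5, seed=7), 1.0)
        for (ma, ta), (mb, tb) in zip(a, b):
            np.testing.assert_array_equal(ma, mb)
            assert ta == tb
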