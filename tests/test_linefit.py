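"""Orientation splitting, least-squares fitting, outlier screening, errors."""

import numpy as np
import pytest

from fieldseg.boundary import label_regions, trace_boundary
from fieldseg.linefit import (OrientationRule, PolynomialLine, angular_error,
                              fit_line_ls, remove_outliers_and_refit,
                              split_orientation, vertical_error)


def line(orientation, c0, c1):
    return PolynomialLine(orientation=orientation, order=1,
                          coefficients=(c0, c1), support=2)


class TestSplitOrientation:
    def test_rectangle_yields_two_sets_per_orientation(self, rect_mask):
        rm = label_regions(binary=(rect_mask == 2).astype(np.uint8),
                           min_area=1)
        path = trace_boundary(rm, 1)
        rule = OrientationRule(delta_threshold=20, gap_threshold=20)
        h_sets, v_sets = split_orientation(path, rule)
        assert len(h_sets) == 2 and len(v_sets) == 2
        h_levels = sorted(np.median(s[:, 1]) for s in h_sets)
        assert h_levels == [60, 99]          # top and bottom pixel rows
        v_levels = sorted(np.median(s[:, 0]) for s in v_sets)
        assert v_levels == [50, 149]

    def test_corner_points_may_join_both_orientations(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 1                 # 10 x 10 square
        rm = label_regions(mask, min_area=1)
        path = trace_boundary(rm, 1)
        rule = OrientationRule(delta_threshold=50, gap_threshold=50,
                               end_trim=0)
        h_sets, v_sets = split_orientation(path, rule)
        h_pts = {tuple(p) for s in h_sets for p in s}
        v_pts = {tuple(p) for s in v_sets for p in s}
        assert (5.0, 5.0) in h_pts and (5.0, 5.0) in v_pts

    def test_short_path_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            split_orientation(np.array([[0, 0], [1, 0], [2, 0]]),
                              OrientationRule())


class TestFitLineLS:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        pts = np.stack([x, 2 * x + 1], axis=1)
        fitted, diag = fit_line_ls(pts, order=1)
        assert fitted.coefficients == pytest.approx((1.0, 2.0))
        assert diag.sse == pytest.approx(0.0, abs=1e-18)

    def test_constant_line(self):
        pts = np.stack([np.arange(8.0), np.full(8, 5.0)], axis=1)
        fitted, _ = fit_line_ls(pts, order=1)
        assert fitted.coefficients == pytest.approx((5.0, 0.0))

    def test_vertical_orientation_swaps_frame(self):
        y = np.arange(12.0)
        pts = np.stack([0.5 * y + 3, y], axis=1)       # x = 3 + 0.5 y
        fitted, _ = fit_line_ls(pts, order=1, orientation="vertical")
        assert fitted.coefficients == pytest.approx((3.0, 0.5))

    def test_noisy_slope_recovered_within_bound(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.linspace(0, 199, 200)
            y = 30 + 0.2 * x + rng.normal(0, 1.0, size=200)
            fitted, _ = fit_line_ls(np.stack([x, y], axis=1), order=1)
            assert abs(fitted.slope - 0.2) < 0.02

    def test_degenerate_abscissae_rejected(self):
        pts = np.stack([np.full(6, 4.0), np.arange(6.0)], axis=1)
        with pytest.raises(ValueError, match="degenerate orientation"):
            fit_line_ls(pts, order=1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_line_ls(np.array([[0.0, 0.0], [1.0, 1.0]]), order=1)

    def test_fit_minimizes_sse(self, rng):
        pts = np.stack([np.arange(30.0),
                        rng.normal(size=30) + 0.3 * np.arange(30)], axis=1)
        fitted, diag = fit_line_ls(pts, order=1)

        def sse(c0, c1):
            r = pts[:, 1] - (c0 + c1 * pts[:, 0])
            return r @ r

        base = sse(*fitted.coefficients)
        for dc0 in (-1e-3, 1e-3):
            for dc1 in (-1e-3, 1e-3):
                assert sse(fitted.coefficients[0] + dc0,
                           fitted.coefficients[1] + dc1) >= base

    def test_point_order_invariance(self, rng):
        pts = np.stack([np.arange(40.0),
                        rng.normal(size=40) + 0.1 * np.arange(40)], axis=1)
        a, _ = fit_line_ls(pts, order=1)
        b, _ = fit_line_ls(pts[rng.permutation(40)], order=1)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-9)


class TestOutlierScreening:
    def test_single_gross_outlier_removed(self):
        x = np.arange(20.0)
        pts = np.stack([x, 2 * x + 1], axis=1)
        pts = np.vstack([pts, [5.0, 100.0]])
        fitted, diag = remove_outliers_and_refit(pts, order=1)
        assert diag.removed_indices == (20,)
        assert fitted.coefficients == pytest.approx((1.0, 2.0))

    def test_clean_data_is_fixed_point(self, rng):
        pts = np.stack([np.arange(30.0),
                        rng.normal(0, 0.5, 30) + np.arange(30.0)], axis=1)
        robust, diag = remove_outliers_and_refit(pts, order=1)
        plain, _ = fit_line_ls(pts, order=1)
        if not diag.removed_indices:
            np.testing.assert_allclose(robust.coefficients,
                                       plain.coefficients)

    def test_infinite_threshold_equals_plain_fit(self, rng):
        pts = np.stack([np.arange(25.0), rng.normal(size=25)], axis=1)
        robust, diag = remove_outliers_and_refit(pts, order=1,
                                                 z_max=np.inf)
        plain, _ = fit_line_ls(pts, order=1)
        assert diag.removed_indices == ()
        np.testing.assert_allclose(robust.coefficients, plain.coefficients)

    def test_screening_restores_contaminated_fits(self):
        """5% one-sided gross outliers: screened fit stays within 0.5 deg
        wherever the plain fit errs by more than 1 deg."""
        contaminated_cases = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = np.linspace(0, 199, 200)
            y = 40 + 0.1 * x + rng.normal(0, 0.4, 200)
            n_out = 10                       # 5% gross outliers
            # leverage positions (upper half of the span) tilt the fit
            idx = 100 + rng.choice(100, n_out, replace=False)
            y[idx] += rng.uniform(40, 80, n_out)
            pts = np.stack([x, y], axis=1)
            truth = line("horizontal", 40, 0.1)
            plain, _ = fit_line_ls(pts, order=1)
            robust, diag = remove_outliers_and_refit(pts, order=1)
            if angular_error(truth, plain) > 1.0:
                contaminated_cases += 1
                assert angular_error(truth, robust) <= 0.5
            assert len(diag.removed_indices) >= n_out // 2
        assert contaminated_cases >= 10     # the comparison is non-vacuous


class TestErrorMetrics:
    def test_forty_five_degrees(self):
        assert angular_error(line("horizontal", 0, 1),
                             line("horizontal", 0, 0)) == pytest.approx(45.0)

    def test_identical_lines_zero_error(self):
        l = line("horizontal", 3, 0.2)
        assert angular_error(l, l) == 0.0
        assert vertical_error(l, l, 1024) == 0.0

    def test_small_slope_difference(self):
        got = angular_error(line("horizontal", 0, 0.1),
                            line("horizontal", 0, 0.2))
        assert got == pytest.approx(5.599, abs=5e-4)

    def test_vertical_error_arithmetic(self):
        got = vertical_error(line("horizontal", 100, 0),
                             line("horizontal", 104, 0), 1024)
        assert got == pytest.approx(4 / 1024)

    def test_doubling_height_halves_error(self):
        a = line("horizontal", 10, 0)
        b = line("horizontal", 20, 0)
        assert vertical_error(a, b, 512) == pytest.approx(
            2 * vertical_error(a, b, 1024))

    def test_vertical_orientation_normalized_by_width(self):
        a = line("vertical", 10, 0)
        b = line("vertical", 20, 0)
        assert vertical_error(a, b, 100, image_width=200) == pytest.approx(
            10 / 200)

    def test_mixed_orientation_rejected(self):
        with pytest.raises(ValueError, match="mixed orientation"):
            angular_error(line("horizontal", 0, 0), line("vertical", 0, 0))

    def test_angular_error_bounded(self, rng):
        for _ in range(50):
            a = line("horizontal", 0, rng.uniform(-5, 5))
            b = line("horizontal", 0, rng.uniform(-5, 5))
            assert 0.0 <= angular_error(a, b) <= 90.0
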