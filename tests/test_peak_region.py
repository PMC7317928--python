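"""Fitness-surface optimum, Tukey depth, bootstrap region, thin-plate splines."""

import numpy as np
import pytest

from conftest import brute_force_ols
from stabsel.data_model import DataError
from stabsel.peak_region import (
    QuadraticSurface,
    _quad_design,
    bootstrap_peak_region,
    fit_quadratic_surface,
    surface_grid,
    surface_maximum,
    tps_fit,
    tukey_depth,
    tukey_depth_approx,
    tukey_depth_exact_2d,
)


class TestQuadraticSurface:
    def test_exact_recovery_of_generating_quadratic(self, rng):
        X = rng.standard_normal((30, 2))
        y = 1 - (X[:, 0] - 0.2) ** 2 - (X[:, 1] - 0.3) ** 2
        s = fit_quadratic_surface(X, y)
        np.testing.assert_allclose(s.curvature, -np.eye(2), atol=1e-10)
        np.testing.assert_allclose(s.linear, [0.4, 0.6], atol=1e-10)
        np.testing.assert_allclose(s.intercept, 1 - 0.04 - 0.09, atol=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.standard_normal(40)
        s = fit_quadratic_surface(X, y)
        assert abs(s.residuals.sum()) < 1e-10

    def test_matches_design_matrix_oracle(self, rng):
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        s = fit_quadratic_surface(X, y)
        coef = brute_force_ols(_quad_design(X), y)
        np.testing.assert_allclose(s.intercept, coef[0], atol=1e-10)
        np.testing.assert_allclose(s.linear, coef[1:3], atol=1e-10)
        np.testing.assert_allclose(np.diag(s.curvature), coef[3:5], atol=1e-10)
        np.testing.assert_allclose(s.curvature[0, 1], coef[5] / 2, atol=1e-10)

    def test_evaluate_matches_fitted_values(self, rng):
        X = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        s = fit_quadratic_surface(X, y)
        np.testing.assert_allclose(s.evaluate(X), s.fitted, atol=1e-10)


class TestSurfaceMaximum:
    BOX = np.array([[-1.0, 1.0], [-1.0, 1.0]])

    def test_symmetric_bowl_peaks_at_origin(self):
        s = QuadraticSurface(0.0, np.zeros(2), -np.eye(2))
        np.testing.assert_allclose(surface_maximum(s, self.BOX), 0.0,
                                   atol=1e-12)

    def test_interior_peak_returned_exactly(self):
        # y = 1 - (x1 - 0.222)^2 - (x2 - 0.275)^2
        s = QuadraticSurface(1 - 0.222**2 - 0.275**2,
                             np.array([2 * 0.222, 2 * 0.275]), -np.eye(2))
        x, on_boundary = surface_maximum(s, self.BOX, return_boundary_flag=True)
        np.testing.assert_allclose(x, [0.222, 0.275], atol=1e-12)
        assert not on_boundary

    def test_agrees_with_grid_search_oracle(self, rng):
        for _ in range(10):
            A = rng.standard_normal((2, 2))
            curv = -(A @ A.T) - 0.1 * np.eye(2)
            s = QuadraticSurface(0.0, rng.standard_normal(2), curv)
            g = np.linspace(-1, 1, 400)
            XX, YY = np.meshgrid(g, g, indexing="ij")
            pts = np.column_stack([XX.ravel(), YY.ravel()])
            best = pts[np.argmax(s.evaluate(pts))]
            x = surface_maximum(s, self.BOX)
            assert np.abs(x - best).max() < 2 * (g[1] - g[0])

    def test_saddle_maximum_lands_on_boundary_and_is_flagged(self):
        s = QuadraticSurface(0.0, np.zeros(2),
                             np.array([[1.0, 0.0], [0.0, -1.0]]))
        x, on_boundary = surface_maximum(s, self.BOX, return_boundary_flag=True)
        assert on_boundary
        assert abs(abs(x[0]) - 1.0) < 1e-9  # disruptive axis pinned at box edge

    def test_grid_oracle_for_boundary_cases(self, rng):
        for k in range(5):
            A = rng.standard_normal((2, 2))
            s = QuadraticSurface(0.0, rng.standard_normal(2),
                                 0.5 * (A + A.T))  # arbitrary curvature
            g = np.linspace(-1, 1, 400)
            XX, YY = np.meshgrid(g, g, indexing="ij")
            pts = np.column_stack([XX.ravel(), YY.ravel()])
            val_oracle = s.evaluate(pts).max()
            x = surface_maximum(s, self.BOX)
            assert s.evaluate(x[None])[0] >= val_oracle - 1e-6


class TestTukeyDepth:
    def test_center_of_symmetric_cloud_is_half(self, rng):
        pts = rng.standard_normal((401, 2))
        cloud = np.vstack([pts, -pts, [[0.0, 0.0]]])
        depth = tukey_depth_approx(cloud, n_directions=2000, seed=1)
        assert abs(depth[-1] - 0.5) < 0.01

    def test_approx_upper_bounds_exact_2d(self, rng):
        cloud = rng.standard_normal((50, 2))
        exact = tukey_depth_exact_2d(cloud)
        approx = tukey_depth_approx(cloud, n_directions=10_000, seed=0)
        assert np.all(approx >= exact - 1e-12)
        assert np.abs(approx - exact).max() <= 1 / 50 + 1e-12

    def test_hull_vertex_attains_minimum_depth(self, rng):
        cloud = rng.standard_normal((50, 2))
        extreme = int(np.argmax(cloud[:, 0]))  # a hull vertex
        depth = tukey_depth_approx(cloud, n_directions=10_000, seed=2)
        assert depth[extreme] == pytest.approx(1 / 50)

    def test_depth_invariant_under_joint_rotation(self, rng):
        cloud = rng.standard_normal((60, 3))
        U = rng.standard_normal((3, 500))
        U /= np.linalg.norm(U, axis=0, keepdims=True)
        R = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        d1 = tukey_depth(cloud, U)
        d2 = tukey_depth(cloud @ R.T, R @ U)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_more_directions_never_increase_depth(self, rng):
        cloud = rng.standard_normal((40, 2))
        rng2 = np.random.default_rng(0)
        U = rng2.standard_normal((2, 4000))
        U /= np.linalg.norm(U, axis=0, keepdims=True)
        d_few = tukey_depth(cloud, U[:, :500])
        d_many = tukey_depth(cloud, U)  # superset of the first 500
        assert np.all(d_many <= d_few + 1e-12)


class TestBootstrapPeakRegion:
    def _data(self, rng, n=300, noise=0.5):
        X = rng.standard_normal((n, 2))
        y = 1 - 0.4 * ((X[:, 0] - 0.3) ** 2 + (X[:, 1] + 0.2) ** 2)
        return X, y + noise * rng.standard_normal(n)

    def test_retained_count_is_round_retain_times_b(self, rng):
        X, y = self._data(rng)
        region = bootstrap_peak_region(X, y, B=200, retain=0.95,
                                       n_directions=500, seed=0)
        assert region.n_retained == round(0.95 * 200)

    def test_zero_noise_collapses_to_a_point(self, rng):
        X = rng.standard_normal((50, 2))
        y = 1 - (X[:, 0] - 0.1) ** 2 - (X[:, 1] - 0.2) ** 2  # exact quadratic
        region = bootstrap_peak_region(X, y, B=100, retain=0.95,
                                       n_directions=500, seed=0)
        assert region.degenerate
        np.testing.assert_allclose(region.centroid, [0.1, 0.2], atol=1e-8)
        assert region.contains([0.1, 0.2])

    def test_centroid_lies_inside_hull(self, rng):
        X, y = self._data(rng)
        region = bootstrap_peak_region(X, y, B=300, retain=0.95,
                                       n_directions=1000, seed=4)
        assert region.contains(region.centroid)

    def test_hull_contains_every_retained_maximum(self, rng):
        X, y = self._data(rng)
        region = bootstrap_peak_region(X, y, B=200, retain=0.9,
                                       n_directions=1000, seed=5)
        for pt in region.maxima_cloud:
            assert region.contains(pt)

    def test_reproducible_from_seed(self, rng):
        X, y = self._data(rng)
        a = bootstrap_peak_region(X, y, B=150, retain=0.9, n_directions=500,
                                  seed=9)
        b = bootstrap_peak_region(X, y, B=150, retain=0.9, n_directions=500,
                                  seed=9)
        np.testing.assert_array_equal(a.maxima_cloud, b.maxima_cloud)

    def test_bounds_must_cover_observations(self, rng):
        X, y = self._data(rng)
        with pytest.raises(DataError, match="cover"):
            bootstrap_peak_region(X, y, B=100, bounds=[[0, 1], [0, 1]])


class TestThinPlateSpline:
    def test_interpolates_at_zero_smoothing(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        s = tps_fit(X, y, smoothing=0.0)
        np.testing.assert_allclose(s.evaluate(X), y, atol=1e-8)

    def test_large_smoothing_tends_to_affine_fit(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        s = tps_fit(X, y, smoothing=1e8)
        P = np.column_stack([np.ones(30), X])
        affine = P @ brute_force_ols(P, y)
        np.testing.assert_allclose(s.evaluate(X), affine, atol=1e-4)

    def test_gcv_choice_matches_per_basis_oracle(self, rng):
        # oracle: rebuild the influence matrix column by column by
        # smoothing each unit vector through the fitting path, then
        # compute the GCV score directly
        X = rng.standard_normal((25, 2))
        y = np.sin(X[:, 0]) + 0.3 * rng.standard_normal(25)
        grid = np.logspace(-6, 1, 15)
        s = tps_fit(X, y, smoothing="gcv", gcv_grid=grid)

        def gcv_oracle(lam):
            n = len(y)
            A = np.empty((n, n))
            for j in range(n):
                e = np.zeros(n)
                e[j] = 1.0
                A[:, j] = tps_fit(X, e, smoothing=lam).evaluate(X)
            return n * float(((y - A @ y) ** 2).sum()) / np.trace(
                np.eye(n) - A) ** 2

        scores = [gcv_oracle(lam) for lam in grid]
        assert s.smoothing == pytest.approx(grid[int(np.argmin(scores))])

    def test_duplicate_sites_interpolation_rejected(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(DataError, match="duplicate"):
            tps_fit(X, np.arange(4.0), smoothing=0.0)

    def test_fewer_than_four_sites_rejected(self, rng):
        with pytest.raises(DataError):
            tps_fit(rng.standard_normal((3, 2)), np.zeros(3), smoothing=0.1)


class TestSurfaceGrid:
    def test_resolution_three_unit_square(self):
        s = QuadraticSurface(0.0, np.zeros(2), np.zeros((2, 2)))
        grid = surface_grid(s, 3, [[0, 1], [0, 1]])
        assert grid.shape == (9, 3)
        np.testing.assert_allclose(grid[0, :2], [0, 0])
        np.testing.assert_allclose(grid[4, :2], [0.5, 0.5])
        np.testing.assert_allclose(grid[-1, :2], [1, 1])

    def test_quadratic_grid_equals_direct_evaluation(self, rng):
        s = QuadraticSurface(0.5, rng.standard_normal(2), -np.eye(2))
        grid = surface_grid(s, 5, [[-1, 1], [-1, 1]])
        np.testing.assert_allclose(grid[:, 2], s.evaluate(grid[:, :2]),
                                   atol=1e-12)

    def test_tps_grid_matches_pointwise_evaluation(self, rng):
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        s = tps_fit(X, y, smoothing=0.01)
        grid = surface_grid(s, 4, [[-1, 1], [-1, 1]])
        np.testing.assert_allclose(grid[:, 2], s.evaluate(grid[:, :2]),
                                   atol=1e-10)
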