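import math

import numpy as np
import pytest

from scotomap.geometry import FieldPoint
from scotomap.observer import ScotomaObserver
from scotomap.validation import (
    HeatMapGrid,
    VisibilityMatrix,
    blind_spot_from_heatmap,
    build_heatmap_grid,
    fit_sigmoid,
    run_heatmap,
    run_scaling,
    scaling_coefficients,
    zero_visible_size,
)


def cells_inside_ellipse_oracle(grid, cx, cy, w, h):
    """Cells entirely inside the ellipse, decided from corner membership.

    For an axis-aligned rectangle vs an axis-aligned ellipse, all four
    corners inside implies the whole cell is inside (the ellipse is convex).
    """
    a, b = w / 2, h / 2
    members = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            x0, y0, x1, y1 = grid.cell_rect(r, c)
            corners = [(x0, y0), (x1, y0), (x0, y1), (x1, y1)]
            if all(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 < 1 for x, y in corners):
                members.append((r, c))
    return members


class TestGrid:
    def test_margins_and_cell_size(self):
        g = build_heatmap_grid(FieldPoint(0, 0), 10.0, 10.0, 10, 10)
        assert (g.width, g.height) == (11.0, 12.0)
        assert (g.cell_width, g.cell_height) == pytest.approx((1.1, 1.2))

    def test_canonical_cell_dimensions(self):
        g = build_heatmap_grid(FieldPoint(16, -2), 6.6, 7.6, 10, 10)
        assert round(g.cell_width, 2) == 0.73
        assert g.cell_height == pytest.approx(0.92, abs=0.01)
        assert g.width == pytest.approx(7.26)

    def test_cells_tile_exactly(self):
        g = build_heatmap_grid(FieldPoint(1.0, -2.0), 6.28, 7.02, 7, 9)
        area = sum(
            (r[2] - r[0]) * (r[3] - r[1])
            for r in (g.cell_rect(i, j) for i in range(g.rows) for j in range(g.cols))
        )
        assert area == pytest.approx(g.width * g.height)
        # adjacent cells share edges exactly (no gaps, no overlap)
        for i in range(g.rows):
            for j in range(g.cols - 1):
                assert g.cell_rect(i, j)[2] == pytest.approx(g.cell_rect(i, j + 1)[0])
        for i in range(g.rows - 1):
            for j in range(g.cols):
                assert g.cell_rect(i, j)[1] == pytest.approx(g.cell_rect(i + 1, j)[3])

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_heatmap_grid(FieldPoint(0, 0), -1.0, 5.0)


class TestRunHeatmap:
    def test_sharp_observer_extremes(self, sharp_observer, rng):
        o = sharp_observer
        grid = build_heatmap_grid(o.center, o.width, o.height, 10, 10)
        m = run_heatmap(grid, o, rng, trials_per_cell=2)
        # centre cells strictly inside -> 0; corner cells fully outside -> 1
        assert m.values[4, 4] == 0.0 and m.values[5, 5] == 0.0
        assert m.values[0, 0] == 1.0 and m.values[-1, -1] == 1.0

    def test_trial_accounting(self, sharp_observer, rng):
        grid = build_heatmap_grid(sharp_observer.center, 6.28, 7.02, 5, 4)
        m = run_heatmap(grid, sharp_observer, rng, trials_per_cell=3)
        assert len(m.log) == 5 * 4 * 3
        assert np.all((m.values * 3) == np.round(m.values * 3))

    def test_guess_rate_sets_inside_cell_rate(self, rng):
        # an interior cell's visibility is Binomial(n, guess)/n for a sharp
        # observer with guesses; pool many repetitions to pin the rate
        o = ScotomaObserver(
            boundary_slope=0.0, lapse_rate=0.0, guess_rate=0.1, fixation_jitter_sd=0.0
        )
        grid = HeatMapGrid(o.center, 1.0, 1.0, 1, 1)  # one cell deep inside
        vals = [run_heatmap(grid, o, rng, trials_per_cell=10).values[0, 0] for _ in range(500)]
        assert np.mean(vals) == pytest.approx(0.10, abs=0.03)


class TestBlindSpotFromHeatmap:
    def test_single_center_cell(self):
        grid = HeatMapGrid(FieldPoint(0, 0), 3.0, 3.0, 3, 3)
        m = VisibilityMatrix(np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float), 10)
        est = blind_spot_from_heatmap(m, grid)
        assert est.cells == [(1, 1)]
        assert (est.width, est.height) == (1.0, 1.0)

    def test_all_visible_empty_region(self):
        grid = HeatMapGrid(FieldPoint(0, 0), 3.0, 3.0, 3, 3)
        m = VisibilityMatrix(np.ones((3, 3)), 10)
        est = blind_spot_from_heatmap(m, grid)
        assert est.cells == [] and est.width == 0.0 and est.height == 0.0

    def test_matches_cell_membership_oracle(self, sharp_observer, rng):
        o = sharp_observer
        grid = build_heatmap_grid(o.center, o.width, o.height, 15, 15)
        m = run_heatmap(grid, o, rng, trials_per_cell=1)
        est = blind_spot_from_heatmap(m, grid)
        assert sorted(est.cells) == cells_inside_ellipse_oracle(
            grid, o.center.x, o.center.y, o.width, o.height
        )

    def test_sizes_converge_with_resolution(self, sharp_observer, rng):
        """Finer grids shrink the size error toward zero in degrees.

        The sub-threshold region of a sharp observer is the set of cells
        entirely inside the ellipse, so each side can lose up to one cell
        of partial coverage plus the quantisation of the outer edge: the
        error is bounded by two cells per dimension and non-increasing
        with resolution (in cell units it oscillates with how the grid
        lines align with the ellipse apices, so one cell is not a bound).
        """
        o = sharp_observer
        errors = {}
        for n in (10, 20, 40):
            grid = build_heatmap_grid(o.center, o.width, o.height, n, n)
            m = run_heatmap(grid, o, rng, trials_per_cell=1)
            est = blind_spot_from_heatmap(m, grid)
            err = max(abs(est.width - o.width), abs(est.height - o.height))
            errors[n] = (err, max(grid.cell_width, grid.cell_height))
        assert errors[40][0] <= errors[20][0] <= errors[10][0]
        for n in (10, 20, 40):
            assert errors[n][0] <= 2 * errors[n][1]


class TestScaling:
    def test_default_coefficients(self):
        c = scaling_coefficients()
        assert c[0] == 0.6 and c[-1] == 1.2
        assert np.allclose(np.diff(c), 0.6 / 9)
        # the canonical grid contains ~0.67, ~0.87, ~1.07
        for target in (0.6667, 0.8667, 1.0667):
            assert np.min(np.abs(c - target)) < 1e-3

    def test_two_point_grid(self):
        assert list(scaling_coefficients(2)) == [0.6, 1.2]

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            scaling_coefficients(10, 1.2, 0.6)

    def test_sharp_observer_containment(self, sharp_observer, rng):
        o = sharp_observer
        res = run_scaling(o.center, o.width, o.height, o, rng)
        assert len(res.log) == 100
        below = res.coefficients < 1.0
        assert np.all(res.proportions[below] == 0.0)
        assert np.all(res.proportions[res.coefficients > 1.0] == 1.0)

    def test_noise_free_monotone_in_size(self, sharp_observer, rng):
        res = run_scaling(sharp_observer.center, 6.28, 7.02, sharp_observer, rng)
        assert np.all(np.diff(res.proportions) >= 0)

    def test_jitter_raises_visibility_at_full_size(self, default_observer):
        # gaze jitter makes the full-size ellipse protrude on some trials
        at_06, at_10 = [], []
        for seed in range(100):
            o = default_observer
            res = run_scaling(o.center, o.width, o.height, o, np.random.default_rng(seed))
            at_06.append(res.proportions[0])
            at_10.append(res.proportions[6])  # coefficient closest to 1.0
        assert np.mean(at_10) > np.mean(at_06)


class TestSigmoidFit:
    def test_exact_recovery_from_noiseless_curve(self):
        sizes = scaling_coefficients()
        true = 1.0 / (1.0 + np.exp(-10.0 * (sizes - 0.8)))
        fit = fit_sigmoid(sizes, true)
        assert fit.t == pytest.approx(10.0, abs=1e-6)
        assert fit.x0 == pytest.approx(0.8, abs=1e-6)
        assert fit.predict(fit.x0) == pytest.approx(50.0, abs=1e-9)

    def test_half_visibility_at_inflection(self):
        sizes = scaling_coefficients()
        props = [0, 0, 0, 0, 0.1, 0.3, 0.6, 0.9, 1, 1]
        fit = fit_sigmoid(sizes, props)
        assert fit.predict(fit.x0) == pytest.approx(50.0, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        sizes = scaling_coefficients()
        props = np.array([0, 0, 0, 0, 0.1, 0.3, 0.6, 0.9, 1, 1], dtype=float)
        fit = fit_sigmoid(sizes, props)
        # brute-force SSE oracle over (t, x0)
        ts = np.linspace(1, 60, 240)
        x0s = np.linspace(0.6, 1.2, 241)
        T, X = np.meshgrid(ts, x0s)
        sse = np.array(
            [
                np.sum((100 * props - 100 / (1 + np.exp(-t * (sizes - x0)))) ** 2)
                for t, x0 in zip(T.ravel(), X.ravel())
            ]
        )
        best = sse.min()
        ours = np.sum((100 * props - fit.predict(sizes)) ** 2)
        assert ours <= best + 1e-6
        assert 0.87 <= fit.x0 <= 1.0

    def test_degenerate_data_rejected(self):
        sizes = scaling_coefficients()
        with pytest.raises(ValueError):
            fit_sigmoid(sizes, np.zeros(10))


class TestZeroVisibleSize:
    def test_prefix_of_zeros(self):
        sizes = scaling_coefficients()
        assert zero_visible_size(sizes, [0, 0, 0, 0.1, 0.2, 0.5, 0.8, 1, 1, 1]) == pytest.approx(
            sizes[2]
        )

    def test_all_zero(self):
        sizes = scaling_coefficients()
        assert zero_visible_size(sizes, np.zeros(10)) == 1.2

    def test_undefined_when_smallest_size_seen(self):
        sizes = scaling_coefficients()
        assert zero_visible_size(sizes, [0.1] + [1.0] * 9) is None
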