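import math

import numpy as np
import pytest

from scotomap.border import TestPath as ProbePath
from scotomap.border import (
    DEFAULT_PRIOR,
    ClickRecord,
    DegenerateClustersError,
    FieldRect,
    PathMissesScotomaError,
    cluster_clicks,
    estimate_location_and_size,
    plan_low_mode_path,
    plan_medium_mode_paths,
    run_border_detection,
    simulate_probe_run,
)
from scotomap.geometry import FieldPoint
from scotomap.observer import ScotomaObserver


def ellipse_crossings_oracle(cx, cy, w, h, orientation, anchor):
    """Closed-form ellipse/line intersection, written independently."""
    a, b = w / 2, h / 2
    if orientation == "horizontal":
        t = (anchor - cy) / b
        if abs(t) >= 1:
            return None
        d = a * math.sqrt(1 - t * t)
        return (cx - d, cx + d)
    t = (anchor - cx) / a
    if abs(t) >= 1:
        return None
    d = b * math.sqrt(1 - t * t)
    return (cy - d, cy + d)


def clicks_at(xs, y):
    return [
        ClickRecord(FieldPoint(x, y), "forward", "disappear", 1, 1) for x in xs
    ]


class TestPathPlanning:
    def test_path1_through_prior_center(self):
        p1 = plan_low_mode_path(1, DEFAULT_PRIOR)
        assert p1.orientation == "horizontal"
        assert p1.anchor == -2.0

    def test_path2_through_midpoint_of_path1_points(self):
        pts = {1: (FieldPoint(13, -2), FieldPoint(19, -2))}
        p2 = plan_low_mode_path(2, DEFAULT_PRIOR, pts)
        assert p2.orientation == "vertical"
        assert p2.anchor == 16.0

    def test_path3_through_midpoint_of_path2_points(self):
        pts = {2: (FieldPoint(16, 1.5), FieldPoint(16, -5.5))}
        p3 = plan_low_mode_path(3, DEFAULT_PRIOR, pts)
        assert p3.orientation == "horizontal"
        assert p3.anchor == -2.0

    def test_prerequisites_enforced(self):
        with pytest.raises(ValueError):
            plan_low_mode_path(2, DEFAULT_PRIOR, {})
        with pytest.raises(ValueError):
            plan_low_mode_path(3, DEFAULT_PRIOR, {1: (FieldPoint(13, -2), FieldPoint(19, -2))})

    def test_medium_adds_four_quarter_axis_paths(self):
        extra = plan_medium_mode_paths(FieldPoint(16, -2), 6.0, 7.0)
        assert [p.index for p in extra] == [4, 5, 6, 7]
        assert sorted(p.anchor for p in extra if p.orientation == "vertical") == [14.5, 17.5]
        assert sorted(p.anchor for p in extra if p.orientation == "horizontal") == [-3.75, -0.25]


class TestClusterClicks:
    def test_two_group_means(self):
        cs = clicks_at([12.9, 13.1, 13.0, 18.9, 19.1, 19.0], -2.0)
        inner, outer = cluster_clicks(cs)
        assert inner == FieldPoint(13.0, -2.0)
        assert outer == FieldPoint(19.0, -2.0)

    def test_inner_is_nearer_fixation(self):
        cs = clicks_at([19.0, 19.1, 12.9, 13.0], -2.0)
        inner, outer = cluster_clicks(cs)
        assert inner.x < outer.x

    def test_degenerate_cluster_rejected(self):
        cs = clicks_at([15.0, 15.02, 15.05, 15.08, 15.03, 15.06], -2.0)
        with pytest.raises(DegenerateClustersError):
            cluster_clicks(cs)

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            cluster_clicks(clicks_at([13.0, 13.1, 19.0, 19.1, 19.2], -2.0))

    def test_minimum_click_count(self):
        with pytest.raises(ValueError):
            cluster_clicks(clicks_at([13.0, 19.0], -2.0))


class TestSimulateProbeRun:
    def test_click_accounting(self, sharp_observer, rng):
        path = ProbePath(1, "horizontal", -2.0, 12.0, 20.0)
        clicks = simulate_probe_run(path, sharp_observer, 3, rng)
        assert len(clicks) == 12  # 2 clicks x 2 passes x 3 round trips
        inner, outer = cluster_clicks(clicks, "horizontal")
        # 6 clicks per border point
        assert sum(1 for c in clicks if c.position.x < 16) == 6

    def test_noise_free_clicks_on_true_crossings(self, sharp_observer, rng):
        o = sharp_observer
        path = ProbePath(1, "horizontal", -2.0, 12.0, 20.0)
        lo, hi = ellipse_crossings_oracle(o.center.x, o.center.y, o.width, o.height, "horizontal", -2.0)
        for c in simulate_probe_run(path, o, 2, rng):
            assert min(abs(c.position.x - lo), abs(c.position.x - hi)) < 1e-9

    def test_missed_path_raises(self, sharp_observer, rng):
        path = ProbePath(1, "horizontal", 30.0, 12.0, 20.0)
        with pytest.raises(PathMissesScotomaError):
            simulate_probe_run(path, sharp_observer, 1, rng)


class TestEstimateLocationAndSize:
    def test_cardinal_construction(self):
        p2 = ProbePath(2, "vertical", 16.0, -6.0, 2.0)
        p3 = ProbePath(3, "horizontal", -2.0, 12.0, 20.0)
        pts2 = (FieldPoint(16, 1.5), FieldPoint(16, -5.5))
        pts3 = (FieldPoint(13, -2), FieldPoint(19, -2))
        loc, w, h = estimate_location_and_size(p2, p3, pts2, pts3)
        assert loc == FieldPoint(16.0, -2.0)
        assert (w, h) == (6.0, 7.0)

    def test_parallel_paths_rejected(self):
        p2 = ProbePath(2, "horizontal", -2.0, 12.0, 20.0)
        p3 = ProbePath(3, "horizontal", -2.0, 12.0, 20.0)
        pts = (FieldPoint(13, -2), FieldPoint(19, -2))
        with pytest.raises(ValueError):
            estimate_location_and_size(p2, p3, pts, pts)

    def test_coincident_points_rejected(self):
        p2 = ProbePath(2, "vertical", 16.0, -6.0, 2.0)
        p3 = ProbePath(3, "horizontal", -2.0, 12.0, 20.0)
        with pytest.raises(ValueError):
            estimate_location_and_size(
                p2, p3, (FieldPoint(16, 0), FieldPoint(16, 0)), (FieldPoint(13, -2), FieldPoint(19, -2))
            )


class TestFullDetection:
    def test_noise_free_low_mode_recovers_truth(self, sharp_observer, rng):
        det = run_border_detection(sharp_observer, rng, "low")
        assert det.location.x == pytest.approx(16.00, abs=0.05)
        assert det.location.y == pytest.approx(-2.05, abs=0.05)
        assert det.width == pytest.approx(6.28, abs=1e-9)
        assert det.height == pytest.approx(7.02, abs=1e-9)

    def test_noise_free_medium_points_on_true_ellipse(self, sharp_observer, rng):
        o = sharp_observer
        det = run_border_detection(o, rng, "medium")
        pts = det.raw_points.all_points()
        assert len(pts) == 14
        for p in pts:
            r = math.hypot(
                (p.x - o.center.x) / (o.width / 2), (p.y - o.center.y) / (o.height / 2)
            )
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_location_invariant_to_prior_shift(self, sharp_observer):
        base = run_border_detection(sharp_observer, np.random.default_rng(0), "low")
        shifted_prior = FieldRect(12.7, 20.7, -5.2, 2.8)
        shifted = run_border_detection(
            sharp_observer, np.random.default_rng(0), "low", prior=shifted_prior
        )
        assert shifted.location.x == pytest.approx(base.location.x, abs=1e-9)
        assert shifted.location.y == pytest.approx(base.location.y, abs=1e-9)

    def test_parameter_recovery_under_default_noise(self, default_observer):
        o = default_observer
        loc_errs, rel_errs = [], []
        for seed in range(200):
            det = run_border_detection(o, np.random.default_rng(seed), "low")
            loc_errs.append((det.location - o.center).norm())
            rel_errs.append(abs(det.width - o.width) / o.width)
            rel_errs.append(abs(det.height - o.height) / o.height)
        assert np.median(loc_errs) <= o.fixation_jitter_sd
        assert np.median(rel_errs) <= 0.05
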