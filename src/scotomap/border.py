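"""Three-step moving-probe border-point detection.

The observer sweeps a small probe forth and back along straight test
paths crossing the blind spot and clicks where it perceptually disappears
and reappears.  Paths are planned sequentially: a first horizontal pass
through the prior search region, a vertical path through the midpoint of
the first pair of border points, and a second horizontal path through the
midpoint of the vertical pair.  The intersection of paths 2 and 3 is the
estimated blind-spot location; their border-point separations give height
and width.  "Medium" mode adds four more paths (quarter-axis offsets) for
14 border points in 7 paths; "High" adds another four (eighth-axis
offsets, experimental) for 22 points in 11 paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import FieldPoint
from .observer import ScotomaObserver

__all__ = [
    "TestPath",
    "ClickRecord",
    "BorderPointSet",
    "FieldRect",
    "PathMissesScotomaError",
    "DegenerateClustersError",
    "DEFAULT_PRIOR",
    "MODE_PATH_COUNTS",
    "MODE_POINT_COUNTS",
    "plan_low_mode_path",
    "plan_medium_mode_paths",
    "plan_high_mode_paths",
    "cluster_clicks",
    "simulate_probe_run",
    "estimate_location_and_size",
    "run_border_detection",
    "BorderDetectionResult",
]


class PathMissesScotomaError(RuntimeError):
    """The test path does not cross the scotoma: no visibility transitions."""


class DegenerateClustersError(RuntimeError):
    """Click reports cannot be split into two separated border clusters."""


@dataclass(frozen=True)
class FieldRect:
    """Axis-aligned rectangle in field coordinates (deg)."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("degenerate FieldRect")

    @property
    def center(self) -> FieldPoint:
        return FieldPoint((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)


#: Default prior search region around the canonical right-eye blind spot.
DEFAULT_PRIOR = FieldRect(12.0, 20.0, -6.0, 2.0)

MODE_PATH_COUNTS = {"low": 3, "medium": 7, "high": 11}
MODE_POINT_COUNTS = {"low": 6, "medium": 14, "high": 22}


@dataclass(frozen=True)
class TestPath:
    """One straight probe path.

    ``anchor`` is the fixed coordinate (y for horizontal paths, x for
    vertical ones); ``start``/``end`` bound the free coordinate.
    ``parent`` records which earlier step defined the path.
    """

    index: int
    orientation: str  # "horizontal" | "vertical"
    anchor: float
    start: float
    end: float
    parent: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.start == self.end:
            raise ValueError("path extent must be non-degenerate")

    def point_at(self, coord: float) -> FieldPoint:
        if self.orientation == "horizontal":
            return FieldPoint(coord, self.anchor)
        return FieldPoint(self.anchor, coord)


@dataclass(frozen=True)
class ClickRecord:
    position: FieldPoint
    pass_direction: str  # "forward" | "backward"
    transition: str  # "disappear" | "reappear"
    round_trip_index: int
    path_index: int = 0


@dataclass
class BorderPointSet:
    """Border points by path, at one estimation stage (raw or adjusted)."""

    stage: str
    points: dict[int, tuple[FieldPoint, FieldPoint]] = field(default_factory=dict)

    def all_points(self) -> list[FieldPoint]:
        out: list[FieldPoint] = []
        for inner, outer in self.points.values():
            out.extend((inner, outer))
        return out


def _ellipse_crossings(
    center: FieldPoint, width: float, height: float, orientation: str, anchor: float
) -> tuple[float, float] | None:
    """Free-axis coordinates where a path line crosses the ellipse, or None."""
    a, b = width / 2.0, height / 2.0
    if orientation == "horizontal":
        off, c_free, half = anchor - center.y, center.x, a
        rel = off / b
    else:
        off, c_free, half = anchor - center.x, center.y, b
        rel = off / a
    if abs(rel) >= 1.0:
        return None
    d = half * math.sqrt(1.0 - rel * rel)
    return (c_free - d, c_free + d)


def plan_low_mode_path(
    step: int,
    prior: FieldRect = DEFAULT_PRIOR,
    previous_points: dict[int, tuple[FieldPoint, FieldPoint]] | None = None,
) -> TestPath:
    """Plan path 1, 2 or 3 of the three-step procedure.

    Path 1 runs horizontally through the vertical centre of the prior
    region; path 2 is the vertical line through the midpoint of path 1's
    border points; path 3 the horizontal line through the midpoint of
    path 2's.  Requesting path 2 or 3 before its prerequisite points exist
    raises ``ValueError``.
    """
    previous_points = previous_points or {}
    if step == 1:
        return TestPath(1, "horizontal", prior.center.y, prior.xmin, prior.xmax, "prior")
    if step == 2:
        if 1 not in previous_points:
            raise ValueError("path 2 requires path-1 border points")
        p, q = previous_points[1]
        return TestPath(2, "vertical", (p.x + q.x) / 2.0, prior.ymin, prior.ymax, "path1")
    if step == 3:
        if 2 not in previous_points:
            raise ValueError("path 3 requires path-2 border points")
        p, q = previous_points[2]
        return TestPath(3, "horizontal", (p.y + q.y) / 2.0, prior.xmin, prior.xmax, "path2")
    raise ValueError("low mode has paths 1-3")


def _offset_paths(
    location: FieldPoint,
    width: float,
    height: float,
    prior: FieldRect,
    frac: float,
    first_index: int,
    parent: str,
) -> list[TestPath]:
    return [
        TestPath(first_index, "vertical", location.x - width * frac, prior.ymin, prior.ymax, parent),
        TestPath(first_index + 1, "vertical", location.x + width * frac, prior.ymin, prior.ymax, parent),
        TestPath(first_index + 2, "horizontal", location.y - height * frac, prior.xmin, prior.xmax, parent),
        TestPath(first_index + 3, "horizontal", location.y + height * frac, prior.xmin, prior.xmax, parent),
    ]


def plan_medium_mode_paths(
    location: FieldPoint, width: float, height: float, prior: FieldRect = DEFAULT_PRIOR
) -> list[TestPath]:
    """Paths 4-7: vertical lines at x = cx +/- w/4 and horizontal lines at
    y = cy +/- h/4, sampling the quadrants between the cardinal points."""
    return _offset_paths(location, width, height, prior, 0.25, 4, "low-estimate")


def plan_high_mode_paths(
    location: FieldPoint, width: float, height: float, prior: FieldRect = DEFAULT_PRIOR
) -> list[TestPath]:
    """Paths 8-11 (experimental): offsets at +/- w/8 and h/8."""
    return _offset_paths(location, width, height, prior, 0.125, 8, "low-estimate")


def simulate_probe_run(
    path: TestPath,
    obs: ScotomaObserver,
    round_trips: int,
    rng: np.random.Generator,
    click_bias: float = 0.0,
    fixation_tolerance: float | None = None,
) -> list[ClickRecord]:
    """Simulate the moving-probe sweeps along one path.

    Each round trip is a forward and a backward pass; each pass yields one
    "disappear" and one "reappear" click at the true visibility-transition
    crossings of the path with the scotoma boundary (shifted by the pass's
    gaze error), plus Gaussian click error along the movement direction.
    ``click_bias`` adds a signed mean displacement in the movement
    direction (real observers click late); the default observer has none.

    Raises :class:`PathMissesScotomaError` when the path (under the sampled
    gaze) never crosses the blind spot.
    """
    if round_trips < 1:
        raise ValueError("round_trips must be >= 1")
    clicks: list[ClickRecord] = []
    for trip in range(1, round_trips + 1):
        for direction, name in ((1.0, "forward"), (-1.0, "backward")):
            gaze = _draw_gaze(obs, rng, fixation_tolerance)
            shifted = FieldPoint(obs.center.x + gaze.x, obs.center.y + gaze.y)
            crossing = _ellipse_crossings(shifted, obs.width, obs.height, path.orientation, path.anchor)
            if crossing is None:
                raise PathMissesScotomaError(
                    f"path {path.index} ({path.orientation} at {path.anchor:.2f} deg) "
                    "does not cross the scotoma"
                )
            lo, hi = crossing
            first, second = (lo, hi) if direction > 0 else (hi, lo)
            for coord, transition in ((first, "disappear"), (second, "reappear")):
                noisy = coord + direction * click_bias + rng.normal(0.0, obs.click_error_sd)
                clicks.append(
                    ClickRecord(path.point_at(noisy), name, transition, trip, path.index)
                )
    return clicks


def _draw_gaze(
    obs: ScotomaObserver, rng: np.random.Generator, tolerance: float | None
) -> FieldPoint:
    for _ in range(1000):
        gx, gy = rng.normal(0.0, obs.fixation_jitter_sd, size=2)
        g = FieldPoint(float(gx), float(gy))
        if tolerance is None or g.norm() <= tolerance:
            return g
    raise RuntimeError("could not draw a within-tolerance gaze sample in 1000 attempts")


def cluster_clicks(
    clicks: list[ClickRecord],
    orientation: str | None = None,
    min_separation: float = 0.5,
) -> tuple[FieldPoint, FieldPoint]:
    """Split one path's clicks into the two border-point clusters.

    Clicks are sorted along the path's free axis and split at the largest
    gap (equivalent to lower/upper halves for balanced passes); each group
    is averaged.  The group nearer fixation (the field origin) is returned
    first as the *inner* (nasal/lower) border point.

    Requires an even count of at least 4 clicks; raises
    :class:`DegenerateClustersError` when either cluster would hold fewer
    than two clicks or the cluster means are separated by less than
    ``min_separation`` deg.
    """
    if len(clicks) < 4:
        raise ValueError("need at least 4 clicks to form two border points")
    if len(clicks) % 2:
        raise ValueError("odd click count: unusable pass")
    xs = np.array([c.position.x for c in clicks])
    ys = np.array([c.position.y for c in clicks])
    if orientation is None:
        orientation = "horizontal" if np.ptp(xs) >= np.ptp(ys) else "vertical"
    free = xs if orientation == "horizontal" else ys
    order = np.argsort(free)
    gaps = np.diff(free[order])
    split = int(np.argmax(gaps)) + 1
    if split < 2 or len(clicks) - split < 2:
        raise DegenerateClustersError("largest-gap split leaves a cluster with < 2 clicks")
    lo_idx, hi_idx = order[:split], order[split:]
    lo = FieldPoint(float(xs[lo_idx].mean()), float(ys[lo_idx].mean()))
    hi = FieldPoint(float(xs[hi_idx].mean()), float(ys[hi_idx].mean()))
    if (hi - lo).norm() < min_separation:
        raise DegenerateClustersError(
            f"cluster means separated by less than {min_separation} deg"
        )
    return (lo, hi) if lo.norm() <= hi.norm() else (hi, lo)


def estimate_location_and_size(
    path2: TestPath,
    path3: TestPath,
    points2: tuple[FieldPoint, FieldPoint],
    points3: tuple[FieldPoint, FieldPoint],
) -> tuple[FieldPoint, float, float]:
    """Location and size from the cardinal paths.

    The location is the intersection of the vertical path 2 and horizontal
    path 3; the height is the separation of path 2's border points and the
    width that of path 3's.
    """
    if {path2.orientation, path3.orientation} != {"vertical", "horizontal"}:
        raise ValueError("paths 2 and 3 must be a perpendicular vertical/horizontal pair")
    if path2.orientation == "horizontal":  # accept either argument order
        path2, path3 = path3, path2
        points2, points3 = points3, points2
    location = FieldPoint(path2.anchor, path3.anchor)
    height = abs(points2[0].y - points2[1].y)
    width = abs(points3[0].x - points3[1].x)
    if not (width > 0 and height > 0):
        raise ValueError("coincident border points: non-positive width/height")
    return location, width, height


@dataclass
class BorderDetectionResult:
    mode: str
    paths: list[TestPath]
    clicks: list[ClickRecord]
    raw_points: BorderPointSet
    location: FieldPoint
    width: float
    height: float

    @property
    def cardinal(self) -> dict[str, FieldPoint]:
        """The four cardinal border points keyed left/right/bottom/top."""
        p2 = sorted(self.raw_points.points[2], key=lambda p: p.y)
        p3 = sorted(self.raw_points.points[3], key=lambda p: p.x)
        return {"left": p3[0], "right": p3[1], "bottom": p2[0], "top": p2[1]}


def run_border_detection(
    obs: ScotomaObserver,
    rng: np.random.Generator,
    mode: str = "low",
    prior: FieldRect = DEFAULT_PRIOR,
    round_trips: int = 3,
    click_bias: float = 0.0,
    fixation_tolerance: float | None = None,
) -> BorderDetectionResult:
    """Run the full border-points detection section in the given mode."""
    mode = mode.lower()
    if mode not in MODE_PATH_COUNTS:
        raise ValueError(f"unknown mode {mode!r}")
    points: dict[int, tuple[FieldPoint, FieldPoint]] = {}
    paths: list[TestPath] = []
    clicks: list[ClickRecord] = []

    def run_path(path: TestPath) -> None:
        cs = simulate_probe_run(path, obs, round_trips, rng, click_bias, fixation_tolerance)
        clicks.extend(cs)
        points[path.index] = cluster_clicks(cs, path.orientation)
        paths.append(path)

    for step in (1, 2, 3):
        run_path(plan_low_mode_path(step, prior, points))
    location, width, height = estimate_location_and_size(
        paths[1], paths[2], points[2], points[3]
    )
    if mode in ("medium", "high"):
        for path in plan_medium_mode_paths(location, width, height, prior):
            run_path(path)
    if mode == "high":
        for path in plan_high_mode_paths(location, width, height, prior):
            run_path(path)
    return BorderDetectionResult(
        mode, paths, clicks, BorderPointSet("raw", points), location, width, height
    )
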