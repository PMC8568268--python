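"""Full-block orchestration: border detection -> staircase -> validation.

A *block* runs the three sections in order against a response backend,
passing estimates forward: the detection section yields the location and
raw cardinal border points; the staircase refines each examined border
point toward the location; the validation section (heat map or scaling)
is built on the staircase-adjusted size estimates.  Trials whose gaze
sample exceeds the fixation tolerance (1.5 deg by default, boundary
inclusive) never contribute to estimates and are re-run.

The response backend is any object answering "present stimulus ->
(seen, gaze)"; the packaged backend is the simulated
:class:`~scotomap.observer.ScotomaObserver` (hardware backends are out of
scope but would slot in at the same seam).  A block is deterministic
given (protocol, observer, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FieldPoint, ScreenModel, DEFAULT_SCREEN
from .observer import ScotomaObserver
from .border import (
    DEFAULT_PRIOR,
    FieldRect,
    MODE_PATH_COUNTS,
    MODE_POINT_COUNTS,
    BorderPointSet,
    run_border_detection,
)
from .staircase import StaircaseRules, run_staircase
from .validation import (
    HeatmapEstimate,
    ScalingResult,
    VisibilityMatrix,
    blind_spot_from_heatmap,
    build_heatmap_grid,
    run_heatmap,
    run_scaling,
)

__all__ = [
    "ValidationSpec",
    "BlockProtocol",
    "TrialCounts",
    "BlockResult",
    "expected_trial_counts",
    "fixation_gate",
    "run_block",
]


@dataclass(frozen=True)
class ValidationSpec:
    """Which validation procedure to run, and at what size."""

    kind: str = "scaling"  # "scaling" | "heatmap"
    rows: int = 10
    cols: int = 10
    trials_per_cell: int = 10
    n_sizes: int = 10
    trials_per_size: int = 10
    lo: float = 0.6
    hi: float = 1.2

    def __post_init__(self) -> None:
        if self.kind not in ("scaling", "heatmap"):
            raise ValueError(f"unknown validation kind {self.kind!r}")
        for name in ("rows", "cols", "trials_per_cell", "n_sizes", "trials_per_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class BlockProtocol:
    mode: str = "low"
    round_trips: int = 3
    staircase: StaircaseRules = field(default_factory=StaircaseRules)
    validation: ValidationSpec = field(default_factory=ValidationSpec)
    fixation_tolerance: float = 1.5
    prior: FieldRect = DEFAULT_PRIOR

    def __post_init__(self) -> None:
        if self.mode.lower() not in MODE_PATH_COUNTS:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fixation_tolerance <= 0:
            raise ValueError("fixation tolerance must be positive")
        if self.round_trips < 1:
            raise ValueError("round_trips must be >= 1")


class TrialCounts:
    """Minimum valid-trial counts per section."""

    def __init__(self, detection: int, staircase: int, validation: int) -> None:
        self.detection = detection
        self.staircase = staircase
        self.validation = validation

    def __iter__(self):
        return iter((self.detection, self.staircase, self.validation))

    def __eq__(self, other) -> bool:
        return tuple(self) == tuple(other)

    def __repr__(self) -> str:
        return f"TrialCounts(detection={self.detection}, staircase={self.staircase}, validation={self.validation})"


def expected_trial_counts(protocol: BlockProtocol) -> TrialCounts:
    """Per-section minimum trial counts implied by the protocol.

    Detection counts click events (2 per pass per border point); the
    staircase examines the 4 cardinal points in Low mode and every border
    point in Medium/High; validation is cells x trials-per-cell or
    sizes x trials-per-size.
    """
    mode = protocol.mode.lower()
    n_points = MODE_POINT_COUNTS[mode]
    detection = n_points * 2 * protocol.round_trips
    staircased = 4 if mode == "low" else n_points
    staircase = staircased * protocol.staircase.n_trials
    v = protocol.validation
    if v.kind == "heatmap":
        validation = v.rows * v.cols * v.trials_per_cell
    else:
        validation = v.n_sizes * v.trials_per_size
    return TrialCounts(detection, staircase, validation)


def fixation_gate(gaze_offset: FieldPoint, tolerance: float) -> bool:
    """Trial validity: gaze within ``tolerance`` deg of fixation (inclusive)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    return gaze_offset.norm() <= tolerance


@dataclass
class BlockResult:
    """Everything one block estimates, plus its validation output."""

    mode: str
    location: FieldPoint
    raw_width: float
    raw_height: float
    adj_width: float
    adj_height: float
    raw_points: BorderPointSet
    adjusted_points: BorderPointSet
    raw_cardinal: dict[str, FieldPoint]
    adjusted_cardinal: dict[str, FieldPoint]
    validation: VisibilityMatrix | ScalingResult
    heatmap_estimate: HeatmapEstimate | None
    clicks: pd.DataFrame
    staircase_trace: pd.DataFrame
    counts: TrialCounts

    def to_dict(self) -> dict:
        """JSON-serialisable summary (logs excluded)."""
        d = {
            "mode": self.mode,
            "location": [self.location.x, self.location.y],
            "raw_width": self.raw_width,
            "raw_height": self.raw_height,
            "adj_width": self.adj_width,
            "adj_height": self.adj_height,
            "raw_cardinal": {k: [p.x, p.y] for k, p in self.raw_cardinal.items()},
            "adjusted_cardinal": {k: [p.x, p.y] for k, p in self.adjusted_cardinal.items()},
            "counts": list(self.counts),
        }
        if self.heatmap_estimate is not None:
            d["heatmap_width"] = self.heatmap_estimate.width
            d["heatmap_height"] = self.heatmap_estimate.height
        return d


def _adjusted_cardinal_sizes(adj: dict[str, FieldPoint]) -> tuple[float, float]:
    width = abs(adj["right"].x - adj["left"].x)
    height = abs(adj["top"].y - adj["bottom"].y)
    return width, height


def run_block(
    protocol: BlockProtocol,
    obs: ScotomaObserver,
    rng: np.random.Generator,
    screen: ScreenModel = DEFAULT_SCREEN,
) -> BlockResult:
    """Run one full mapping block against the simulated observer."""
    mode = protocol.mode.lower()
    det = run_border_detection(
        obs,
        rng,
        mode=mode,
        prior=protocol.prior,
        round_trips=protocol.round_trips,
        fixation_tolerance=protocol.fixation_tolerance,
    )

    # Which raw points get staircased: cardinal only in Low, all otherwise.
    if mode == "low":
        staircased = {2: det.raw_points.points[2], 3: det.raw_points.points[3]}
    else:
        staircased = dict(det.raw_points.points)

    adjusted = BorderPointSet("adjusted")
    trace_rows: list[dict] = []
    for path_index, (inner, outer) in sorted(staircased.items()):
        adj_pair = []
        for which, point in (("inner", inner), ("outer", outer)):
            run = run_staircase(
                point,
                det.location,
                obs,
                protocol.staircase,
                rng,
                screen=screen,
                fixation_tolerance=protocol.fixation_tolerance,
            )
            adj_pair.append(run.adjusted_point)
            for row in run.trace:
                trace_rows.append({"path_index": path_index, "point": which, **row})
        adjusted.points[path_index] = (adj_pair[0], adj_pair[1])

    adj_cardinal = {
        "bottom": min(adjusted.points[2], key=lambda p: p.y),
        "top": max(adjusted.points[2], key=lambda p: p.y),
        "left": min(adjusted.points[3], key=lambda p: p.x),
        "right": max(adjusted.points[3], key=lambda p: p.x),
    }
    adj_width, adj_height = _adjusted_cardinal_sizes(adj_cardinal)

    v = protocol.validation
    heat_est = None
    if v.kind == "heatmap":
        grid = build_heatmap_grid(det.location, adj_width, adj_height, v.rows, v.cols)
        result: VisibilityMatrix | ScalingResult = run_heatmap(
            grid, obs, rng, v.trials_per_cell, fixation_tolerance=protocol.fixation_tolerance
        )
        heat_est = blind_spot_from_heatmap(result, grid)
    else:
        result = run_scaling(
            det.location,
            adj_width,
            adj_height,
            obs,
            rng,
            n_sizes=v.n_sizes,
            trials_per_size=v.trials_per_size,
            lo=v.lo,
            hi=v.hi,
            fixation_tolerance=protocol.fixation_tolerance,
        )

    clicks = pd.DataFrame(
        {
            "path_index": [c.path_index for c in det.clicks],
            "round_trip": [c.round_trip_index for c in det.clicks],
            "pass_direction": [c.pass_direction for c in det.clicks],
            "transition": [c.transition for c in det.clicks],
            "x_deg": [c.position.x for c in det.clicks],
            "y_deg": [c.position.y for c in det.clicks],
        }
    )
    return BlockResult(
        mode=mode,
        location=det.location,
        raw_width=det.width,
        raw_height=det.height,
        adj_width=adj_width,
        adj_height=adj_height,
        raw_points=det.raw_points,
        adjusted_points=adjusted,
        raw_cardinal=det.cardinal,
        adjusted_cardinal=adj_cardinal,
        validation=result,
        heatmap_estimate=heat_est,
        clicks=clicks,
        staircase_trace=pd.DataFrame(trace_rows),
        counts=expected_trial_counts(protocol),
    )
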