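"""Precision statistics and study-level aggregation.

The precision of repeated 2-D estimates is summarised by the *standard
distance*,

    Stdist = sqrt( (1/n) * sum_i [ (x_i - xbar)^2 + (y_i - ybar)^2 ] ),

the RMS Euclidean distance of the points from their centroid.  Per-block
estimates are aggregated per observer (means, sample SDs, ranges, Stdist,
and the summed Stdist of the four cardinal border points), then across
observers, where SD-like columns are RMS-aggregated (square root of mean
variances / squared Stdists) and plain columns arithmetically averaged.
The *precision quotient* divides an observer's location Stdist by the
minor axis (the smaller of width and height); the *safe zone* is half the
smallest observed width and height, a central region guaranteed invisible
for every observer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import FieldPoint

__all__ = [
    "BlockEstimates",
    "ObserverSummary",
    "standard_distance",
    "rms_aggregate",
    "precision_quotient",
    "summarize_observer",
    "summarize_study",
    "paired_t",
    "independent_t",
    "safe_zone",
    "load_reference_study",
    "CARDINAL_KEYS",
]

CARDINAL_KEYS = ("left", "right", "bottom", "top")


def standard_distance(points) -> float:
    """Standard distance of a set of 2-D points (deg).

    ``points`` is a sequence of :class:`FieldPoint` or an (n, 2) array.
    A single point has zero standard distance; an empty set is an error.
    Translation- and rotation-invariant by construction.
    """
    arr = np.asarray(
        [(p.x, p.y) if isinstance(p, FieldPoint) else tuple(p) for p in points], dtype=float
    )
    if arr.size == 0:
        raise ValueError("standard_distance of an empty point set")
    centered = arr - arr.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def rms_aggregate(values) -> float:
    """Square root of the mean of squares (for aggregating SDs and Stdists)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("rms_aggregate of an empty list")
    return float(np.sqrt(np.mean(arr**2)))


def precision_quotient(stdist: float, width: float, height: float) -> float:
    """Location Stdist relative to the minor axis length."""
    if not (width > 0 and height > 0):
        raise ValueError("sizes must be positive")
    return stdist / min(width, height)


def safe_zone(widths, heights, coefficient: float = 0.5) -> tuple[float, float]:
    """Half (by default) the smallest observed width and height, rounded to
    2 decimals for reporting.  Stimuli within this centred region are
    expected to be invisible for any observer in the group."""
    widths = list(widths)
    heights = list(heights)
    if not widths or not heights:
        raise ValueError("safe_zone of empty size lists")
    if min(widths) <= 0 or min(heights) <= 0:
        raise ValueError("sizes must be positive")
    return (
        _round2(coefficient * min(widths)),
        _round2(coefficient * min(heights)),
    )


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (reporting convention)."""
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


class TTest(NamedTuple):
    t: float
    df: int
    p: float


def paired_t(a: Sequence[float], b: Sequence[float]) -> TTest:
    """Two-tailed paired t test on equal-length samples (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t needs two equal-length samples of size >= 2")
    if np.var(a - b, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(a, b)
    return TTest(float(res.statistic), a.size - 1, float(res.pvalue))


def independent_t(a: Sequence[float], b: Sequence[float]) -> TTest:
    """Two-tailed pooled-variance two-sample t test (df = n1 + n2 - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("independent_t needs samples of size >= 2 each")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        raise ValueError("both samples constant and equal: t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTest(float(res.statistic), a.size + b.size - 2, float(res.pvalue))


@dataclass(frozen=True)
class BlockEstimates:
    """One block's blind-spot estimates for one observer."""

    observer_id: str
    block_id: str
    location: FieldPoint
    width: float
    height: float
    raw_points: dict[str, FieldPoint]  # keyed by CARDINAL_KEYS
    adjusted_points: dict[str, FieldPoint]

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("block width and height must be positive")


@dataclass(frozen=True)
class ObserverSummary:
    observer_id: str
    n_blocks: int
    loc_h: float
    loc_v: float
    loc_h_sd: float
    loc_v_sd: float
    loc_h_range: tuple[float, float]
    loc_v_range: tuple[float, float]
    loc_stdist: float
    loc_dist_range: tuple[float, float]
    width: float
    width_sd: float
    width_range: tuple[float, float]
    height: float
    height_sd: float
    height_range: tuple[float, float]
    raw_border_sum_stdist: float
    adj_border_sum_stdist: float

    def to_row(self) -> dict:
        row = {
            "observer": self.observer_id,
            "n_blocks": self.n_blocks,
            "loc_h": self.loc_h,
            "loc_v": self.loc_v,
            "loc_h_sd": self.loc_h_sd,
            "loc_v_sd": self.loc_v_sd,
            "loc_stdist": self.loc_stdist,
            "width": self.width,
            "width_sd": self.width_sd,
            "height": self.height,
            "height_sd": self.height_sd,
            "raw_border_sum_stdist": self.raw_border_sum_stdist,
            "adj_border_sum_stdist": self.adj_border_sum_stdist,
        }
        for name, rng_ in (
            ("loc_h", self.loc_h_range),
            ("loc_v", self.loc_v_range),
            ("loc_dist", self.loc_dist_range),
            ("width", self.width_range),
            ("height", self.height_range),
        ):
            row[f"{name}_min"], row[f"{name}_max"] = rng_
        return row


def summarize_observer(blocks: Sequence[BlockEstimates]) -> ObserverSummary:
    """Aggregate one observer's blocks (means, sample SDs, ranges, Stdists).

    The summed border-point Stdist adds the standard distances of each of
    the four cardinal points across blocks, separately for the raw and the
    staircase-adjusted stage.
    """
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks (sample SDs are undefined otherwise)")
    ids = {b.observer_id for b in blocks}
    if len(ids) > 1:
        raise ValueError(f"blocks from multiple observers: {sorted(ids)}")
    locs = np.array([(b.location.x, b.location.y) for b in blocks])
    widths = np.array([b.width for b in blocks])
    heights = np.array([b.height for b in blocks])
    centroid = locs.mean(axis=0)
    dists = np.hypot(*(locs - centroid).T)

    def sum_stdist(stage: str) -> float:
        total = 0.0
        for key in CARDINAL_KEYS:
            pts = [getattr(b, stage)[key] for b in blocks]
            total += standard_distance(pts)
        return total

    return ObserverSummary(
        observer_id=blocks[0].observer_id,
        n_blocks=len(blocks),
        loc_h=float(locs[:, 0].mean()),
        loc_v=float(locs[:, 1].mean()),
        loc_h_sd=float(locs[:, 0].std(ddof=1)),
        loc_v_sd=float(locs[:, 1].std(ddof=1)),
        loc_h_range=(float(locs[:, 0].min()), float(locs[:, 0].max())),
        loc_v_range=(float(locs[:, 1].min()), float(locs[:, 1].max())),
        loc_stdist=standard_distance(locs),
        loc_dist_range=(float(dists.min()), float(dists.max())),
        width=float(widths.mean()),
        width_sd=float(widths.std(ddof=1)),
        width_range=(float(widths.min()), float(widths.max())),
        height=float(heights.mean()),
        height_sd=float(heights.std(ddof=1)),
        height_range=(float(heights.min()), float(heights.max())),
        raw_border_sum_stdist=sum_stdist("raw_points"),
        adj_border_sum_stdist=sum_stdist("adjusted_points"),
    )


_STUDY_COLUMNS = [
    "loc_h",
    "loc_v",
    "loc_h_sd",
    "loc_v_sd",
    "loc_stdist",
    "width",
    "width_sd",
    "height",
    "height_sd",
    "raw_border_sum_stdist",
    "adj_border_sum_stdist",
]


def summarize_study(table: pd.DataFrame) -> dict:
    """Across-observer summary of a per-observer table.

    ``table`` needs one row per observer with at least the columns
    ``loc_h, loc_v, loc_h_sd, loc_v_sd, loc_stdist, width, width_sd,
    height, height_sd, raw_border_sum_stdist, adj_border_sum_stdist``
    (the layout written by :func:`ObserverSummary.to_row` and shipped in
    the bundled reference study).  Plain columns are arithmetically
    averaged; SD and Stdist columns are additionally RMS-aggregated
    (square root of mean variances).  Includes the mean precision
    quotient and the safe zone.
    """
    missing = [c for c in _STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"per-observer table is missing columns: {missing}")
    if len(table) < 2:
        raise ValueError("need at least 2 observers")
    t = table
    quot = t["loc_stdist"] / np.minimum(t["width"], t["height"])
    sz = safe_zone(t["width"], t["height"])
    out = {
        "n_observers": int(len(t)),
        "loc_h_mean": float(t["loc_h"].mean()),
        "loc_h_sd": float(t["loc_h"].std(ddof=1)),
        "loc_h_range": (float(t["loc_h"].min()), float(t["loc_h"].max())),
        "loc_v_mean": float(t["loc_v"].mean()),
        "loc_v_sd": float(t["loc_v"].std(ddof=1)),
        "loc_v_range": (float(t["loc_v"].min()), float(t["loc_v"].max())),
        "loc_h_sd_rms": rms_aggregate(t["loc_h_sd"]),
        "loc_v_sd_rms": rms_aggregate(t["loc_v_sd"]),
        "loc_stdist_mean": float(t["loc_stdist"].mean()),
        "loc_stdist_sd": float(t["loc_stdist"].std(ddof=1)),
        "loc_stdist_rms": rms_aggregate(t["loc_stdist"]),
        "loc_stdist_range": (float(t["loc_stdist"].min()), float(t["loc_stdist"].max())),
        "width_mean": float(t["width"].mean()),
        "width_sd": float(t["width"].std(ddof=1)),
        "width_cv": float(t["width"].std(ddof=1) / t["width"].mean()),
        "width_range": (float(t["width"].min()), float(t["width"].max())),
        "width_sd_mean": float(t["width_sd"].mean()),
        "width_sd_rms": rms_aggregate(t["width_sd"]),
        "height_mean": float(t["height"].mean()),
        "height_sd": float(t["height"].std(ddof=1)),
        "height_cv": float(t["height"].std(ddof=1) / t["height"].mean()),
        "height_range": (float(t["height"].min()), float(t["height"].max())),
        "height_sd_mean": float(t["height_sd"].mean()),
        "height_sd_rms": rms_aggregate(t["height_sd"]),
        "raw_border_sum_stdist_mean": float(t["raw_border_sum_stdist"].mean()),
        "raw_border_sum_stdist_rms": rms_aggregate(t["raw_border_sum_stdist"]),
        "adj_border_sum_stdist_mean": float(t["adj_border_sum_stdist"].mean()),
        "adj_border_sum_stdist_rms": rms_aggregate(t["adj_border_sum_stdist"]),
        "precision_quotient_mean": float(quot.mean()),
        "precision_quotient_sd": float(quot.std(ddof=1)),
        "precision_quotient_range": (float(quot.min()), float(quot.max())),
        "safe_zone_width": sz[0],
        "safe_zone_height": sz[1],
    }
    return out


def load_reference_study() -> pd.DataFrame:
    """Bundled per-observer summaries of a published 12-observer blind-spot
    mapping study (6 blocks per observer, Low mode + scaling validation);
    used as a regression fixture for the aggregation statistics."""
    with resources.files("scotomap.data").joinpath("reference_observers.csv").open() as fh:
        return pd.read_csv(fh)
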